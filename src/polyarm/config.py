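"""YAML/JSON configuration round-tripping for design specifications.

Config keys mirror the tool's input list: K, correction, alpha,
power_type, beta, pi0, delta1, delta0, sigmas, ratios, integer, plots,
quality, plus `allocation` and `assumed_pis` when the ratios are to be
optimised.  Exactly one of `pi0` (Bernoulli) or `sigmas` (normal) selects
the outcome family.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .model import BernoulliOutcome, DesignSpec, InvalidDesignError, NormalOutcome

__all__ = ["spec_to_dict", "spec_from_dict", "load_spec", "save_spec",
           "default_config"]


def default_config() -> dict:
    """The documented default inputs (the worked three-arm example)."""
    return {
        "K": 2, "correction": "dunnett", "alpha": 0.15, "power_type": "marginal",
        "beta": 0.2, "pi0": 0.3, "delta1": 0.15, "delta0": 0.0,
        "ratios": [1.0, 1.0], "integer": False, "plots": False,
        "quality": "medium",
    }


def spec_to_dict(spec: DesignSpec) -> dict:
    d = {
        "K": spec.K, "correction": spec.mcc, "alpha": spec.alpha,
        "power_type": spec.power_type, "beta": spec.beta,
        "delta1": spec.delta1, "delta0": spec.delta0,
        "integer": spec.integer_n, "plots": spec.plots,
        "quality": spec.quality,
    }
    if spec.outcome.family == "bernoulli":
        d["pi0"] = spec.outcome.pi0
    else:
        d["sigmas"] = list(spec.outcome.sigmas)
    if spec.allocation == "explicit":
        d["ratios"] = list(spec.ratios)
    else:
        d["allocation"] = spec.allocation
        if spec.assumed_pis is not None:
            d["assumed_pis"] = list(spec.assumed_pis)
    return d


def spec_from_dict(d: dict) -> DesignSpec:
    d = dict(d)
    has_pi0 = d.get("pi0") is not None
    has_sig = d.get("sigmas") is not None
    if has_pi0 == has_sig:
        raise InvalidDesignError(
            "config must set exactly one of 'pi0' (Bernoulli) or "
            "'sigmas' (normal)")
    outcome = (BernoulliOutcome(float(d["pi0"])) if has_pi0
               else NormalOutcome(tuple(d["sigmas"])))
    allocation = d.get("allocation", "explicit")
    ratios = d.get("ratios")
    return DesignSpec(
        K=int(d["K"]), alpha=float(d["alpha"]), beta=float(d["beta"]),
        delta1=float(d["delta1"]), delta0=float(d["delta0"]),
        mcc=d["correction"], power_type=d["power_type"], outcome=outcome,
        allocation=allocation,
        ratios=tuple(ratios) if ratios is not None else None,
        assumed_pis=(tuple(d["assumed_pis"])
                     if d.get("assumed_pis") is not None else None),
        integer_n=bool(d.get("integer", False)),
        plots=bool(d.get("plots", False)),
        quality=d.get("quality", "medium"))


def load_spec(path) -> DesignSpec:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return spec_from_dict(data)


def save_spec(spec: DesignSpec, path) -> None:
    path = Path(path)
    d = spec_to_dict(spec)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
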