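"""Canonical model presets covering the four stability/modality regimes.

Four feedback families — constant (no feedback), Michaelis-Menten
(non-cooperative), and two Hill (cooperative) parameterizations — are each
combined with the three burst sizes ``mu_star in {1, 6, 11}`` (no burst,
medium, strong).  The parameters were placed directly on the graphical
construction (where ``f/delta`` crosses the identity line and the shifted
lines ``n + mu_star``) so that together the presets realize every quadrant of
{monostable, bistable} x {unimodal, bimodal}, including the two disagreement
regimes: bistable-unimodal and monostable-bimodal with both modes positive.
Every preset is certified by :func:`burstmodes.experiments.classify_regime`
at generation time.
"""

from __future__ import annotations

import json
from pathlib import Path

from .burst_model import BurstyGeneModel, FeedbackFunction

__all__ = [
    "PRESET_FAMILIES",
    "BURST_SIZES",
    "get_preset",
    "iter_presets",
    "generate_presets",
    "EXPECTED_QUADRANTS",
]

#: burst sizes used throughout: no burst / medium-size burst / strong burst
BURST_SIZES = (1.0, 6.0, 11.0)

PRESET_FAMILIES: dict = {
    # no feedback: f constant; always monostable; Fano factor = mu_star
    "no_feedback": {
        "feedback": {"variant": "constant", "b": 20.0},
        "delta": 1.0,
        "volume": 1.0,
    },
    # non-cooperative saturating feedback; always monostable, but medium
    # bursts open a second mode at n = 0
    "noncoop": {
        "feedback": {"variant": "michaelis_menten", "b": 1.0, "v": 40.0, "K": 10.0},
        "delta": 1.0,
        "volume": 1.0,
    },
    # cooperative feedback tuned bistable; strong bursts erase the upper mode
    "coop_bistable": {
        "feedback": {"variant": "hill", "b": 3.0, "v": 40.0, "K": 20.0**4, "h": 4.0},
        "delta": 1.0,
        "volume": 1.0,
    },
    # cooperative feedback tuned monostable; medium bursts create two modes,
    # both at positive copy numbers
    "coop_monostable_bimodal": {
        "feedback": {"variant": "hill", "b": 8.0, "v": 30.0, "K": 15.0**4, "h": 4.0},
        "delta": 1.0,
        "volume": 1.0,
    },
}

#: regimes each (family, mu_star) pair is certified to realize
EXPECTED_QUADRANTS: dict = {
    ("no_feedback", 1.0): "monostable-unimodal",
    ("noncoop", 6.0): "monostable-bimodal",
    ("coop_bistable", 1.0): "bistable-bimodal",
    ("coop_bistable", 11.0): "bistable-unimodal",
    ("coop_monostable_bimodal", 6.0): "monostable-bimodal",
}


def get_preset(name: str, mu_star: float = 1.0) -> BurstyGeneModel:
    """Build the named preset with the given mean burst size."""
    if name not in PRESET_FAMILIES:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(PRESET_FAMILIES)}"
        )
    cfg = PRESET_FAMILIES[name]
    return BurstyGeneModel(
        f=FeedbackFunction.from_dict(cfg["feedback"]),
        mu_star=float(mu_star),
        delta=cfg["delta"],
        volume=cfg["volume"],
    )


def iter_presets():
    """Yield ``(name, mu_star, model)`` for all 4 families x 3 burst sizes."""
    for name in PRESET_FAMILIES:
        for mu in BURST_SIZES:
            yield name, mu, get_preset(name, mu)


def generate_presets(output_dir) -> list:
    """Write all presets with certification metadata; returns written paths.

    Each JSON file records the model parameters plus the certified regime
    (stable fixed-point count, mode count, label).  Raises if the preset
    collection fails to realize all four stability/modality quadrants.
    """
    from .experiments import classify_regime

    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    written = []
    labels: dict = {}
    for name, mu, model in iter_presets():
        regime = classify_regime(model)
        labels[(name, mu)] = regime.label
        record = {
            "name": name,
            "model": model.to_dict(),
            "certification": {
                "n_stable_fixed_points": regime.n_stable_fixed_points,
                "n_modes": regime.n_modes,
                "label": regime.label,
                "mode_positions": list(regime.mode_positions),
            },
        }
        path = output_dir / f"{name}_mu{int(mu)}.json"
        path.write_text(json.dumps(record, indent=2) + "\n")
        written.append(path)
    covered = set(labels.values())
    required = {
        "monostable-unimodal",
        "monostable-bimodal",
        "bistable-unimodal",
        "bistable-bimodal",
    }
    missing = required - covered
    if missing:
        raise RuntimeError(
            f"preset collection fails to realize quadrants {sorted(missing)}; "
            f"certified labels: { {f'{k[0]}@mu{k[1]:g}': v for k, v in labels.items()} }"
        )
    mismatches = {
        k: (labels[k], v) for k, v in EXPECTED_QUADRANTS.items() if labels[k] != v
    }
    if mismatches:
        raise RuntimeError(f"preset certification mismatches: {mismatches}")
    return written
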