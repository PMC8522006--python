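"""Virtual-channel derivations for around-the-ear (cEEGrid) sleep EEG.

A cEEGrid records eight channels R1–R8 against a right-mastoid reference.
Because the electrodes sit close together, single channels carry little of
the large frontal sleep activity; signed linear combinations spanning the
grid ("bipolar derivations") recover it. The standard layouts built here
relabel those combinations after the classical PSG scalp positions they
extrapolate toward (Fp2, F4, C4, P4, O2, all referenced to the right
mastoid M2):

====================  =========================
Fp2_M2                R1
F4_M2                 (R1 + R2)/2 − R6
C4_M2                 (R2 + R3)/2 − (R6 + R7)/2
P4_M2                 (R3 + R4)/2 − R7
O2_M2                 R7 − R8
====================  =========================

The ``cEEGrid+EOG`` layout adds the two periocular EOG electrodes
re-referenced to R6 (standing in for the mastoid); the ``Fpz+EOG`` layout is
the frontal reference montage passed through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .io_formats import Recording

MONTAGE_NAMES = ("Fpz+EOG", "cEEGrid", "cEEGrid+EOG")

CEEGRID_LABELS: tuple[str, ...] = tuple(f"R{i}" for i in range(1, 9))


@dataclass(frozen=True)
class Derivation:
    """A virtual channel: label plus signed weights over raw channel labels."""

    label: str
    weights: dict[str, float]

    def __post_init__(self):
        if not any(w != 0 for w in self.weights.values()):
            raise ValueError(f"derivation {self.label!r} has no nonzero weight")


@dataclass
class MontageSpec:
    """An ordered set of derivations forming one channel layout."""

    name: str
    derivations: list[Derivation]

    def __post_init__(self):
        labels = [d.label for d in self.derivations]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate derivation labels in montage {self.name!r}")

    @property
    def labels(self) -> list[str]:
        return [d.label for d in self.derivations]


_CEEGRID_EEG = [
    Derivation("Fp2_M2", {"R1": 1.0}),
    Derivation("F4_M2", {"R1": 0.5, "R2": 0.5, "R6": -1.0}),
    Derivation("C4_M2", {"R2": 0.5, "R3": 0.5, "R6": -0.5, "R7": -0.5}),
    Derivation("P4_M2", {"R3": 0.5, "R4": 0.5, "R7": -1.0}),
    Derivation("O2_M2", {"R7": 1.0, "R8": -1.0}),
]
_EOG_REREF = [
    Derivation("EOG_L_M2", {"EOG_L": 1.0, "R6": -1.0}),
    Derivation("EOG_R_M2", {"EOG_R": 1.0, "R6": -1.0}),
]
_FPZ_EOG = [
    Derivation("Fpz", {"Fpz": 1.0}),
    Derivation("EOG_L", {"EOG_L": 1.0}),
    Derivation("EOG_R", {"EOG_R": 1.0}),
]


def build_standard_montage(name: str) -> MontageSpec:
    """Return one of the three standard layouts: Fpz+EOG, cEEGrid, cEEGrid+EOG."""
    if name == "Fpz+EOG":
        return MontageSpec(name, list(_FPZ_EOG))
    if name == "cEEGrid":
        return MontageSpec(name, list(_CEEGRID_EEG))
    if name == "cEEGrid+EOG":
        return MontageSpec(name, list(_CEEGRID_EEG) + list(_EOG_REREF))
    raise KeyError(f"unknown montage layout {name!r}; expected one of {MONTAGE_NAMES}")


def apply_montage(rec: Recording, m: MontageSpec) -> Recording:
    """Project a recording through a montage: out_i = Σ_c w_ic · rec[c]."""
    missing = sorted(
        {c for d in m.derivations for c in d.weights} - set(rec.channel_labels)
    )
    if missing:
        raise KeyError(f"montage {m.name!r} references missing channel(s) {missing}")
    out = np.zeros((len(m.derivations), rec.n_samples))
    for i, d in enumerate(m.derivations):
        for ch, w in d.weights.items():
            out[i] += w * rec.channel(ch)
    return Recording(tuple(m.labels), out, rec.fs, rec.start_time)


def enumerate_combinations(labels: tuple[str, ...] = CEEGRID_LABELS) -> list[Derivation]:
    """All single channels and ordered bipolar pairs of a grid.

    For n labels this is n singletons plus C(n, 2) pairs Li − Lj (i < j) in
    the conventional reading order: R1, R1−R2, R2, R1−R3, R2−R3, R3, … — i.e.
    for each k, all pairs ending at Rk followed by Rk itself. Eight cEEGrid
    channels give the 36 combinations used by the correlation topography.
    """
    labels = tuple(labels)
    if len(set(labels)) != len(labels):
        raise ValueError("combination labels must be distinct")
    out: list[Derivation] = []
    for k, lk in enumerate(labels):
        for li in labels[:k]:
            out.append(Derivation(f"{li}-{lk}", {li: 1.0, lk: -1.0}))
        out.append(Derivation(lk, {lk: 1.0}))
    return out


def montage_to_yaml(m: MontageSpec) -> str:
    """Serialize a montage as YAML (label → {channel: weight})."""
    doc = {
        "name": m.name,
        "derivations": [{"label": d.label, "weights": dict(d.weights)} for d in m.derivations],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def montage_from_yaml(text: str) -> MontageSpec:
    doc = yaml.safe_load(text)
    return MontageSpec(
        doc["name"],
        [Derivation(d["label"], {k: float(v) for k, v in d["weights"].items()})
         for d in doc["derivations"]],
    )
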