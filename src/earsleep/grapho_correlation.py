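"""Correlation topography of grapho-elements across ear-EEG combinations.

K-complexes and sleep spindles annotated on the frontal reference channel
(Fpz) are cut into epochs, and each epoch's Fpz trace is correlated with the
same interval of every single cEEGrid channel and every bipolar pair (36
combinations for 8 electrodes). Per-combination coefficients are aggregated
by Fisher-Z averaging: r values are mapped through atanh, averaged, and
mapped back through tanh, which respects the skewed sampling distribution of
the correlation coefficient. The resulting topography shows which ear-EEG
combinations best represent frontal sleep grapho-elements: combinations
pointing toward Fpz correlate positively, rear-pointing ones negatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import EventAnnotation, Recording
from .montage import CEEGRID_LABELS, Derivation, enumerate_combinations
from .preprocessing import remove_dc

#: atanh argument clip: correlations of exactly ±1 are pulled just inside.
_R_CLIP = 1.0 - 1e-12


@dataclass
class EventEpoch:
    """One grapho-element interval: the Fpz reference trace plus raw grid traces."""

    event: EventAnnotation
    reference: np.ndarray
    raw: dict[str, np.ndarray]
    fs: float

    def __post_init__(self):
        n = len(self.reference)
        if n < 2:
            raise ValueError("epoch must span at least 2 samples")
        for lb, tr in self.raw.items():
            if len(tr) != n:
                raise ValueError(f"trace {lb} length {len(tr)} != reference length {n}")


@dataclass
class CorrelationTopography:
    """Fisher-averaged correlation per combination label, in listing order."""

    element: str
    values: dict[str, float]
    n_epochs: int
    grouping: str = "per-recording"


def extract_epochs(
    rec: Recording,
    events: list[EventAnnotation],
    reference: str = "Fpz",
    raw_labels: tuple[str, ...] = CEEGRID_LABELS,
) -> list[EventEpoch]:
    """Cut the recording into DC-free event epochs.

    The sample window of an event is [round(onset·fs), round((onset+duration)·fs));
    the per-epoch mean is subtracted from the reference and every raw trace.
    """
    for lb in (reference, *raw_labels):
        rec.channel(lb)  # raises KeyError naming the channel
    epochs = []
    for ev in events:
        a = int(round(ev.onset * rec.fs))
        b = int(round((ev.onset + ev.duration) * rec.fs))
        if a < 0 or b > rec.n_samples:
            raise IndexError(
                f"event {ev} spans samples [{a}, {b}) outside recording "
                f"of {rec.n_samples} samples"
            )
        epochs.append(
            EventEpoch(
                event=ev,
                reference=remove_dc(rec.channel(reference)[a:b]),
                raw={lb: remove_dc(rec.channel(lb)[a:b]) for lb in raw_labels},
                fs=rec.fs,
            )
        )
    return epochs


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(xd @ xd)
    sy = float(yd @ yd)
    if sx == 0.0 or sy == 0.0:
        return math.nan  # undefined, reported as missing — never silently 0
    return float((xd @ yd) / math.sqrt(sx * sy))


def correlate_epoch(
    epoch: EventEpoch, combos: list[Derivation] | None = None
) -> dict[str, float]:
    """Pearson r between the reference trace and every derived combination.

    Zero-variance combinations yield NaN (missing), which downstream
    averaging excludes rather than imputes.
    """
    if combos is None:
        combos = enumerate_combinations(tuple(epoch.raw))
    out: dict[str, float] = {}
    for d in combos:
        trace = np.zeros_like(epoch.reference)
        for ch, w in d.weights.items():
            trace = trace + w * epoch.raw[ch]
        out[d.label] = _pearson(epoch.reference, trace)
    return out


def fisher_average(rs) -> float:
    """tanh(mean(atanh(r))): the Fisher-Z average of correlation coefficients.

    Values of exactly ±1 are clipped just inside the open interval so the
    transform stays finite.
    """
    rs = np.asarray(list(rs), dtype=float)
    if rs.size == 0:
        raise ValueError("cannot Fisher-average an empty list")
    if np.any(np.isnan(rs)):
        raise ValueError("NaN correlation passed to fisher_average; filter missing values first")
    if np.any(np.abs(rs) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(rs, -_R_CLIP, _R_CLIP))
    return float(np.tanh(z.mean()))


def topography(
    rec: Recording,
    events: list[EventAnnotation],
    element_label: str,
    combos: list[Derivation] | None = None,
    reference: str = "Fpz",
) -> CorrelationTopography:
    """Per-combination Fisher average over all epochs of one grapho-element."""
    selected = [e for e in events if e.label == element_label]
    if not selected:
        raise ValueError(f"no events labeled {element_label!r}")
    if combos is None:
        combos = enumerate_combinations()
    epochs = extract_epochs(rec, selected, reference=reference)
    per_epoch = [correlate_epoch(ep, combos) for ep in epochs]
    values = {}
    for d in combos:
        rs = [pe[d.label] for pe in per_epoch if not math.isnan(pe[d.label])]
        values[d.label] = fisher_average(rs) if rs else math.nan
    return CorrelationTopography(element_label, values, len(epochs))


def grand_average(topos: list[CorrelationTopography]) -> CorrelationTopography:
    """Fisher-average per-participant topographies into a grand topography."""
    if not topos:
        raise ValueError("need at least one topography")
    elements = {t.element for t in topos}
    if len(elements) > 1:
        raise ValueError(f"mixed elements {sorted(elements)}")
    labels = list(topos[0].values)
    values = {}
    for lb in labels:
        rs = [t.values[lb] for t in topos if not math.isnan(t.values[lb])]
        values[lb] = fisher_average(rs) if rs else math.nan
    return CorrelationTopography(
        topos[0].element, values, sum(t.n_epochs for t in topos), grouping="grand-average"
    )
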