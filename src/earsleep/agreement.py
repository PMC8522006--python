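"""Inter-rater agreement statistics for sleep hypnograms.

Two hypnograms of the same night are aligned epoch-by-epoch, tallied into a
confusion matrix over the six-category alphabet (Art, W, N1, N2, N3, REM),
and summarised with Cohen's kappa

    κ = (p_o − p_e) / (1 − p_e),

where p_o is the observed agreement proportion and p_e the agreement
expected from the two raters' marginal stage frequencies. The standard
error uses the Fleiss–Cohen–Everitt asymptotic variance of unweighted κ.
Per-stage agreement is the κ of the matrix collapsed to "stage versus all
other labels" (artifact epochs count toward the rest). Verbal agreement
bands follow the Landis–Koch scale. Cross-participant agreement is computed
on concatenated hypnograms — equivalently, on the elementwise sum of the
per-participant confusion matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import STAGES, Hypnogram


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows are rater A's labels, columns rater B's."""

    counts: np.ndarray
    labels: tuple[str, ...] = STAGES

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.labels = tuple(self.labels)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {k} labels"
            )
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")
        if self.total <= 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("cannot add confusion matrices with different labels")
        return ConfusionMatrix(self.counts + other.counts, self.labels)


@dataclass(frozen=True)
class AgreementResult:
    """Cohen's kappa with its asymptotic SE and the quantities behind it."""

    kappa: float
    se: float
    po: float
    pe: float
    n: int
    label: str


def align(h1: Hypnogram, h2: Hypnogram, max_epochs: int | None = None):
    """Pair two hypnograms epoch-by-epoch, truncating to the common length.

    ``max_epochs`` expresses per-participant truncation (e.g. keeping only
    the first 5 h 20 min = 640 thirty-second epochs when the tail of one
    recording is unusable).
    """
    if h1.epoch_length != h2.epoch_length:
        raise ValueError(
            f"epoch lengths differ: {h1.epoch_length} vs {h2.epoch_length}"
        )
    n = min(len(h1), len(h2))
    if max_epochs is not None:
        n = min(n, max_epochs)
    if n == 0:
        raise ValueError("hypnograms have no overlapping epochs")
    return list(zip(h1.stages[:n], h2.stages[:n]))


def confusion(pairs, labels: tuple[str, ...] = STAGES) -> ConfusionMatrix:
    """Tally (rater A, rater B) label pairs into a confusion matrix."""
    idx = {lb: i for i, lb in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for a, b in pairs:
        if a not in idx or b not in idx:
            raise ValueError(f"label pair ({a!r}, {b!r}) outside alphabet {labels}")
        counts[idx[a], idx[b]] += 1
    return ConfusionMatrix(counts, labels)


def landis_koch_label(kappa: float) -> str:
    """Verbal band for a kappa value (Landis–Koch convention)."""
    if not -1 <= kappa <= 1:
        raise ValueError(f"kappa {kappa} outside [-1, 1]")
    if kappa <= 0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def cohen_kappa(m: ConfusionMatrix) -> AgreementResult:
    """Unweighted Cohen's kappa with Fleiss–Cohen–Everitt asymptotic SE."""
    n = m.total
    p = m.counts.astype(float) / n
    po = float(np.trace(p))
    prow = p.sum(axis=1)
    pcol = p.sum(axis=0)
    pe = float(prow @ pcol)
    if 1.0 - pe <= 0:
        raise ZeroDivisionError(
            "kappa undefined: chance agreement pe = 1 (degenerate margins)"
        )
    kappa = (po - pe) / (1.0 - pe)

    k = len(m.labels)
    t1 = sum(
        p[i, i] * (1.0 - (prow[i] + pcol[i]) * (1.0 - kappa)) ** 2 for i in range(k)
    )
    t2 = (1.0 - kappa) ** 2 * sum(
        p[i, j] * (pcol[i] + prow[j]) ** 2
        for i in range(k)
        for j in range(k)
        if i != j
    )
    t3 = (kappa - pe * (1.0 - kappa)) ** 2
    var = (t1 + t2 - t3) / (n * (1.0 - pe) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    return AgreementResult(kappa, se, po, pe, n, landis_koch_label(kappa))


def collapse_one_vs_rest(m: ConfusionMatrix, stage: str) -> ConfusionMatrix:
    """Collapse a multi-class matrix to 2×2: ``stage`` versus everything else."""
    if stage not in m.labels:
        raise KeyError(f"stage {stage!r} not among labels {m.labels}")
    i = m.labels.index(stage)
    a = int(m.counts[i, i])
    b = int(m.counts[i, :].sum() - a)
    c = int(m.counts[:, i].sum() - a)
    d = int(m.total - a - b - c)
    return ConfusionMatrix(np.array([[a, b], [c, d]]), (stage, "rest"))


def one_vs_rest_kappa(m: ConfusionMatrix, stage: str) -> AgreementResult:
    """Cohen's kappa of one stage against the pool of all other labels."""
    two = collapse_one_vs_rest(m, stage)
    if two.counts[0, :].sum() == 0 and two.counts[:, 0].sum() == 0:
        raise ZeroDivisionError(f"stage {stage!r} absent from both ratings")
    return cohen_kappa(two)


def paired_t_onetailed(kappas_a, kappas_b) -> tuple[float, float]:
    """Paired one-tailed t-test for mean(kappas_b) > mean(kappas_a).

    The pairing is by participant: each index holds the two per-participant
    kappas under the conditions being compared.
    """
    a = np.asarray(kappas_a, dtype=float)
    b = np.asarray(kappas_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of at least 2 paired values")
    d = b - a
    if np.std(d) <= 1e-12 * max(1.0, float(np.abs(d).max())):
        raise ZeroDivisionError("paired differences have zero variance; t undefined")
    res = stats.ttest_rel(b, a, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def agreement_report(h1: Hypnogram, h2: Hypnogram, max_epochs: int | None = None) -> dict:
    """Full agreement summary of two hypnograms as a JSON-friendly dict."""
    m = confusion(align(h1, h2, max_epochs))
    overall = cohen_kappa(m)
    per_stage = {}
    for s in STAGES[1:]:  # the AASM sleep stages; Art is pooled into "rest"
        try:
            r = one_vs_rest_kappa(m, s)
        except ZeroDivisionError:
            continue
        per_stage[s] = {"kappa": r.kappa, "se": r.se, "label": r.label}
    return {
        "n_epochs": overall.n,
        "kappa": overall.kappa,
        "se": overall.se,
        "po": overall.po,
        "pe": overall.pe,
        "label": overall.label,
        "per_stage": per_stage,
        "confusion": {
            "labels": list(m.labels),
            "counts": m.counts.tolist(),
        },
    }
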