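"""Small-sample replicate statistics for detection experiments.

Detection training runs are expensive, so published comparisons often rest
on as few as three replicate AP@0.5 values per training condition.  This
module implements the statistical harness for exactly that regime:

* the Shapiro–Wilk normality check, with the exact closed form at n = 3:
  ``W = 0.5 (x_(3) - x_(1))^2 / sum (x_i - mean)^2`` and
  ``p = (6/pi) (asin(sqrt(W)) - asin(sqrt(0.75)))``;
* the paired two-sided Student's t-test on replicate triples, pairing
  replicates by index (replicate k of condition A against replicate k of
  condition B);
* a comparison-plan runner producing a method → p-value report from a
  replicate table.

A reference replicate table of AP@0.5 values for incremental training
conditions (base dataset, classic augmentation, style transfer, Pix2Pix
compositing, supervised self-labeling) ships as a fixture, together with the
standard incremental comparison plan, plus two bits of bookkeeping
arithmetic used around such experiments: relative AP drop under a strain
change, and dataset-split totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as _spstats

__all__ = [
    "ReplicateTable",
    "NormalityResult",
    "PairedTestResult",
    "ComparisonRow",
    "shapiro_wilk_n3",
    "shapiro_wilk",
    "paired_t_test",
    "compare_methods",
    "reference_table",
    "REFERENCE_PLAN",
    "relative_drop_percent",
    "dataset_split_total",
    "stylized_image_count",
]


@dataclass(frozen=True)
class NormalityResult:
    W: float
    p: float


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float


@dataclass
class ReplicateTable:
    """Method label → validation AP and three test-replicate AP@0.5 values."""

    rows: dict[str, dict]  # label -> {"val": float, "test": (r1, r2, r3)}

    def __post_init__(self) -> None:
        for label, row in self.rows.items():
            reps = row["test"]
            if len(reps) != 3:
                raise ValueError(f"{label!r}: expected 3 test replicates, got {len(reps)}")
            for v in (row["val"], *reps):
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{label!r}: AP {v} outside [0, 1]")

    def test_replicates(self, label: str) -> tuple[float, float, float]:
        return tuple(self.rows[label]["test"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReplicateTable":
        rows: dict[str, dict] = {}
        lines = Path(path).read_text().splitlines()
        header = lines[0].split("\t")
        if header != ["method", "val", "test_1", "test_2", "test_3"]:
            raise ValueError(f"unexpected replicate-table header: {header}")
        for line in lines[1:]:
            if not line.strip():
                continue
            label, val, r1, r2, r3 = line.split("\t")
            rows[label] = {"val": float(val), "test": (float(r1), float(r2), float(r3))}
        return cls(rows)


def reference_table() -> ReplicateTable:
    """The packaged reference table of replicate AP@0.5 values."""
    with resources.as_file(
        resources.files("wormsynth.data") / "replicate_ap_table.tsv"
    ) as p:
        return ReplicateTable.from_tsv(p)


#: Incremental comparison plan: each proposed method against the condition it
#: extends (style transfer and Pix2Pix against classic augmentation alone;
#: self-labeling against style transfer + Pix2Pix together).
REFERENCE_PLAN: list[tuple[str, str, str]] = [
    ("Style Transfer", "BD + ST", "BD with data augmentation"),
    ("Pix2Pix", "BD + P2P", "BD with data augmentation"),
    ("Self-labeling", "BD + ST + P2P + SSL", "BD + ST + P2P"),
]


def shapiro_wilk_n3(x: Sequence[float]) -> NormalityResult:
    """Exact Shapiro–Wilk test for a sample of exactly three values.

    At n = 3 the W statistic reduces to half the squared range over the sum
    of squared deviations, and the p-value has the closed form
    ``(6/pi) (asin(sqrt(W)) - asin(sqrt(3/4)))``.  W ranges over (0.75, 1],
    hitting 1 for an equally spaced triple.
    """
    x = [float(v) for v in x]
    if len(x) != 3:
        raise ValueError(f"shapiro_wilk_n3 requires exactly 3 values, got {len(x)}")
    if not all(math.isfinite(v) for v in x):
        raise ValueError("values must be finite")
    mean = sum(x) / 3.0
    ss = sum((v - mean) ** 2 for v in x)
    if ss == 0.0:
        raise ValueError("zero variance: all three values are equal")
    w = 0.5 * (max(x) - min(x)) ** 2 / ss
    w = min(w, 1.0)  # guard float round-off at the equally-spaced boundary
    p = (6.0 / math.pi) * (math.asin(math.sqrt(w)) - math.asin(math.sqrt(0.75)))
    return NormalityResult(W=w, p=min(max(p, 0.0), 1.0))


def shapiro_wilk(x: Sequence[float]) -> NormalityResult:
    """Shapiro–Wilk normality test; exact closed form at n = 3, Royston's
    approximation (scipy) otherwise."""
    if len(x) == 3:
        return shapiro_wilk_n3(x)
    w, p = _spstats.shapiro(np.asarray(x, dtype=float))
    return NormalityResult(W=float(w), p=float(p))


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> PairedTestResult:
    """Two-sided paired Student's t-test, pairing samples by index.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``d = b - a`` and the n-1
    standard-deviation denominator; df = n - 1.  Zero difference variance
    (e.g. a constant shift) is an error rather than an infinite statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"samples must be 1-D of equal length, got {a.shape} vs {b.shape}")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = b - a
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance of paired differences")
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * float(_spstats.t.sf(abs(t), df))
    return PairedTestResult(t=float(t), df=df, p=p)


@dataclass(frozen=True)
class ComparisonRow:
    method: str
    p: float
    t: float
    df: int
    normality_method: NormalityResult
    normality_baseline: NormalityResult


def compare_methods(
    table: ReplicateTable, plan: Sequence[tuple[str, str, str]] = tuple(REFERENCE_PLAN)
) -> list[ComparisonRow]:
    """Run the comparison plan: normality check on both rows, then the paired
    t-test of method replicates against baseline replicates.

    Each plan entry is ``(report label, method row, baseline row)``; the
    output has one row per entry, mirroring a method → p-value summary table.
    """
    out: list[ComparisonRow] = []
    for label, method_row, baseline_row in plan:
        m = table.test_replicates(method_row)
        b = table.test_replicates(baseline_row)
        res = paired_t_test(b, m)
        out.append(
            ComparisonRow(
                method=label,
                p=res.p,
                t=res.t,
                df=res.df,
                normality_method=shapiro_wilk(m),
                normality_baseline=shapiro_wilk(b),
            )
        )
    return out


# ---------------------------------------------------------------------------
# bookkeeping arithmetic


def relative_drop_percent(ap_reference: float, ap_degraded: float) -> float:
    """Relative AP drop, in percent: ``100 (ref - new) / ref``.

    Used to quantify robustness to a strain change — how much AP is lost
    when evaluating on a morphologically different strain than trained on.
    """
    if ap_reference <= 0:
        raise ValueError("reference AP must be positive")
    return 100.0 * (ap_reference - ap_degraded) / ap_reference


def dataset_split_total(*split_sizes: int) -> int:
    """Total image count across dataset splits."""
    return sum(split_sizes)


def stylized_image_count(n_train_images: int, styles_per_image: int = 5) -> int:
    """Images produced by applying ``styles_per_image`` styles to each
    training image."""
    return n_train_images * styles_per_image
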