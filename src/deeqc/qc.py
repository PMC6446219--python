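"""Per-run quality metrics and the eight-rule pass/warn/fail classifier.

Each run is summarised by eight metrics and screened against heuristic
thresholds.  Read-count thresholds scale with transcriptome complexity:
a run fails rule 1 when it has fewer than 50 QC-passed reads per
protein-coding gene and warns below 500 per gene, and likewise for the
assigned-read rules.  Rate rules use fixed percentages.  All comparisons
are strict ``<`` — a metric exactly at a threshold is not flagged.  Rule 8
(correlation of the run's RPM profile to the average profile of passing
runs) is advisory: it can warn but never fail a run.

=====  ====================  =============  =============
code   metric                fail below     warn below
=====  ====================  =============  =============
1      NumReadsQcPass        50 * G         500 * G
2      QcPassRate            0.60           0.80
3      STAR_UniqMapRate      0.50           0.70
4      STAR_AssignRate       0.40           0.60
5      STAR_AssignedReads    50 * G         500 * G
6      Kallisto_MapRate      0.40           0.60
7      Kallisto_MappedReads  50 * G         500 * G
8      DatasetCorrel         --             0.5
=====  ====================  =============  =============

G is the number of protein-coding genes in the annotation (all genes, for
toy references).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor, log10

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, rpm

#: (code, field, fail threshold, warn threshold); count thresholds in reads
#: per gene, rate thresholds as fractions, None = no fail level.
RULES: list[tuple[int, str, float | None, float, bool]] = [
    (1, "NumReadsQcPass", 50.0, 500.0, True),
    (2, "QcPassRate", 0.60, 0.80, False),
    (3, "STAR_UniqMapRate", 0.50, 0.70, False),
    (4, "STAR_AssignRate", 0.40, 0.60, False),
    (5, "STAR_AssignedReads", 50.0, 500.0, True),
    (6, "Kallisto_MapRate", 0.40, 0.60, False),
    (7, "Kallisto_MappedReads", 50.0, 500.0, True),
    (8, "DatasetCorrel", None, 0.5, False),
]


@dataclass
class QcMetricSet:
    NumReadsQcPass: int
    QcPassRate: float
    STAR_UniqMapRate: float
    STAR_AssignRate: float
    STAR_AssignedReads: int
    Kallisto_MapRate: float
    Kallisto_MappedReads: float
    DatasetCorrel: float | None  # None = not yet computed / undefined
    n_genes: int  # transcriptome complexity G

    def validate(self) -> None:
        for name in ("QcPassRate", "STAR_UniqMapRate", "STAR_AssignRate", "Kallisto_MapRate"):
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"missing metric {name}")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0, 1]: {v}")
        for name in ("NumReadsQcPass", "STAR_AssignedReads", "Kallisto_MappedReads"):
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"missing metric {name}")
            if v < 0:
                raise ValueError(f"{name} negative: {v}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


@dataclass
class QcClassification:
    status: str  # "pass", "warn", "fail"
    codes: set[int] = field(default_factory=set)
    levels: dict[int, str] = field(default_factory=dict)  # code -> "warn"/"fail"

    def passes_rules_1_to_7(self) -> bool:
        return not any(1 <= c <= 7 for c in self.codes)


def classify(m: QcMetricSet) -> QcClassification:
    """Apply the eight rules in code order; strict inequalities throughout."""
    m.validate()
    codes: set[int] = set()
    levels: dict[int, str] = {}
    for code, name, fail_thr, warn_thr, per_gene in RULES:
        value = getattr(m, name)
        if value is None:
            if code == 8:
                continue  # advisory rule is NA-tolerant
            raise ValueError(f"missing metric {name}")
        scale = m.n_genes if per_gene else 1.0
        if fail_thr is not None and value < fail_thr * scale:
            codes.add(code)
            levels[code] = "fail"
        elif value < warn_thr * scale:
            codes.add(code)
            levels[code] = "warn"
    if any(lvl == "fail" for lvl in levels.values()):
        status = "fail"
    elif codes:
        status = "warn"
    else:
        status = "pass"
    return QcClassification(status, codes, levels)


@dataclass
class PassAverageProfile:
    profile: pd.Series  # per-gene mean RPM
    n_runs: int


def build_pass_average(
    matrix: ExpressionMatrix,
    classifications: dict[str, QcClassification],
    max_runs: int = 10000,
    rng_seed: int = 0,
) -> PassAverageProfile:
    """Mean RPM profile of runs passing rules 1-7, subsampled to ``max_runs``.

    Rule 8 is excluded from eligibility because it is what the profile is
    built to compute.
    """
    eligible = [r for r in matrix.samples
                if r in classifications and classifications[r].passes_rules_1_to_7()]
    if not eligible:
        raise ValueError("no runs pass rules 1-7; cannot build a pass-average profile")
    if len(eligible) > max_runs:
        rng = np.random.default_rng(rng_seed)
        eligible = sorted(rng.choice(eligible, size=max_runs, replace=False))
    sub = ExpressionMatrix(matrix.values[eligible], matrix.level)
    normed = rpm(sub)
    return PassAverageProfile(normed.values.mean(axis=1), len(eligible))


def round_sigfigs(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (round-half-even via float round)."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    return round(x, sig - 1 - floor(log10(abs(x))))


def dataset_correl(run_counts: pd.Series, avg: PassAverageProfile) -> float | None:
    """Pearson r of a run's RPM profile to the pass average, 2 significant figures.

    The run's raw counts are RPM-normalised here, making the statistic
    invariant to library size.  Returns None (NA) when either vector has
    zero variance.
    """
    common = run_counts.index.intersection(avg.profile.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 shared genes")
    x = run_counts.loc[common].to_numpy(dtype=float)
    total = x.sum()
    if total <= 0:
        return None
    x = x * 1e6 / total
    y = avg.profile.loc[common].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return round_sigfigs(r, 2)


def metrics_table(metrics: dict[str, QcMetricSet],
                  classifications: dict[str, QcClassification]) -> pd.DataFrame:
    """QC summary table: one row per run, metric columns plus status and codes."""
    rows = {}
    for run, m in metrics.items():
        c = classifications[run]
        rows[run] = {
            "NumReadsQcPass": m.NumReadsQcPass,
            "QcPassRate": m.QcPassRate,
            "STAR_UniqMapRate": m.STAR_UniqMapRate,
            "STAR_AssignRate": m.STAR_AssignRate,
            "STAR_AssignedReads": m.STAR_AssignedReads,
            "Kallisto_MapRate": m.Kallisto_MapRate,
            "Kallisto_MappedReads": m.Kallisto_MappedReads,
            "DatasetCorrel": m.DatasetCorrel if m.DatasetCorrel is not None else pd.NA,
            "status": c.status,
            "codes": ",".join(str(c_) for c_ in sorted(c.codes)),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "run"
    return df
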