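"""Eight-rule classifier: worked examples, boundaries, oracle agreement."""

import math

import numpy as np
import pandas as pd
import pytest

from deeqc import qc
from deeqc.expression import ExpressionMatrix


def clean_metrics(G: int = 100, **overrides) -> qc.QcMetricSet:
    """A metric set comfortably clear of every threshold."""
    m = qc.QcMetricSet(
        NumReadsQcPass=1000 * G,
        QcPassRate=0.95,
        STAR_UniqMapRate=0.85,
        STAR_AssignRate=0.70,
        STAR_AssignedReads=1000 * G,
        Kallisto_MapRate=0.70,
        Kallisto_MappedReads=1000.0 * G,
        DatasetCorrel=0.9,
        n_genes=G,
    )
    for k, v in overrides.items():
        setattr(m, k, v)
    return m


def brute_force_classify(m: qc.QcMetricSet) -> tuple[str, dict[int, str]]:
    """Independent literal re-reading of the rule table, one if-chain per code."""
    G = m.n_genes
    levels: dict[int, str] = {}
    if m.NumReadsQcPass < 50 * G:
        levels[1] = "fail"
    elif m.NumReadsQcPass < 500 * G:
        levels[1] = "warn"
    if m.QcPassRate < 0.60:
        levels[2] = "fail"
    elif m.QcPassRate < 0.80:
        levels[2] = "warn"
    if m.STAR_UniqMapRate < 0.50:
        levels[3] = "fail"
    elif m.STAR_UniqMapRate < 0.70:
        levels[3] = "warn"
    if m.STAR_AssignRate < 0.40:
        levels[4] = "fail"
    elif m.STAR_AssignRate < 0.60:
        levels[4] = "warn"
    if m.STAR_AssignedReads < 50 * G:
        levels[5] = "fail"
    elif m.STAR_AssignedReads < 500 * G:
        levels[5] = "warn"
    if m.Kallisto_MapRate < 0.40:
        levels[6] = "fail"
    elif m.Kallisto_MapRate < 0.60:
        levels[6] = "warn"
    if m.Kallisto_MappedReads < 50 * G:
        levels[7] = "fail"
    elif m.Kallisto_MappedReads < 500 * G:
        levels[7] = "warn"
    if m.DatasetCorrel is not None and m.DatasetCorrel < 0.5:
        levels[8] = "warn"
    if "fail" in levels.values():
        status = "fail"
    elif levels:
        status = "warn"
    else:
        status = "pass"
    return status, levels


class TestClassifyExamples:
    def test_low_pass_rate_fails_code_2(self):
        c = qc.classify(clean_metrics(QcPassRate=0.55))
        assert (c.status, c.codes) == ("fail", {2})

    def test_reads_per_gene_scaling_code_1(self):
        c = qc.classify(clean_metrics(G=100, NumReadsQcPass=4_999))
        assert c.status == "fail" and c.levels[1] == "fail"

    def test_exact_thresholds_all_pass(self):
        m = clean_metrics(
            G=100, NumReadsQcPass=50_000, QcPassRate=0.80, STAR_UniqMapRate=0.70,
            STAR_AssignRate=0.60, STAR_AssignedReads=50_000, Kallisto_MapRate=0.60,
            Kallisto_MappedReads=50_000.0, DatasetCorrel=0.5)
        c = qc.classify(m)
        assert (c.status, c.codes) == ("pass", set())

    def test_low_correlation_warns_code_8(self):
        c = qc.classify(clean_metrics(DatasetCorrel=0.49))
        assert (c.status, c.codes) == ("warn", {8})

    def test_correlation_na_skips_rule_8(self):
        c = qc.classify(clean_metrics(DatasetCorrel=None))
        assert c.status == "pass"

    def test_rule_8_never_fails(self):
        c = qc.classify(clean_metrics(DatasetCorrel=-1.0))
        assert c.status == "warn" and c.levels[8] == "warn"

    def test_missing_metric_named(self):
        m = clean_metrics()
        m.STAR_AssignRate = None
        with pytest.raises(ValueError, match="STAR_AssignRate"):
            qc.classify(m)


# (field, warn threshold, fail threshold, per-gene scaling, count-valued)
BOUNDARY_CASES = [
    (1, "NumReadsQcPass", 500, 50, True),
    (2, "QcPassRate", 0.80, 0.60, False),
    (3, "STAR_UniqMapRate", 0.70, 0.50, False),
    (4, "STAR_AssignRate", 0.60, 0.40, False),
    (5, "STAR_AssignedReads", 500, 50, True),
    (6, "Kallisto_MapRate", 0.60, 0.40, False),
    (7, "Kallisto_MappedReads", 500, 50, True),
]


class TestBoundaries:
    """At each threshold the rule must not trigger; just below, it must."""

    G = 40

    @pytest.mark.parametrize("code,field,warn_thr,fail_thr,per_gene", BOUNDARY_CASES)
    def test_warn_boundary(self, code, field, warn_thr, fail_thr, per_gene):
        scale = self.G if per_gene else 1
        eps = 1 if per_gene else 1e-9
        at = qc.classify(clean_metrics(self.G, **{field: warn_thr * scale}))
        assert code not in at.codes
        below = qc.classify(clean_metrics(self.G, **{field: warn_thr * scale - eps}))
        assert below.levels.get(code) == "warn"

    @pytest.mark.parametrize("code,field,warn_thr,fail_thr,per_gene", BOUNDARY_CASES)
    def test_fail_boundary(self, code, field, warn_thr, fail_thr, per_gene):
        scale = self.G if per_gene else 1
        eps = 1 if per_gene else 1e-9
        at = qc.classify(clean_metrics(self.G, **{field: fail_thr * scale}))
        assert at.levels.get(code) == "warn"  # at the fail line: warn zone
        below = qc.classify(clean_metrics(self.G, **{field: fail_thr * scale - eps}))
        assert below.levels.get(code) == "fail"

    def test_correl_warn_boundary(self):
        assert 8 not in qc.classify(clean_metrics(DatasetCorrel=0.5)).codes
        assert qc.classify(clean_metrics(DatasetCorrel=0.5 - 1e-9)).levels[8] == "warn"


def random_metrics(rng: np.random.Generator) -> qc.QcMetricSet:
    G = int(rng.integers(1, 200))
    return qc.QcMetricSet(
        NumReadsQcPass=int(rng.integers(0, 1000 * G)),
        QcPassRate=float(rng.uniform(0, 1)),
        STAR_UniqMapRate=float(rng.uniform(0, 1)),
        STAR_AssignRate=float(rng.uniform(0, 1)),
        STAR_AssignedReads=int(rng.integers(0, 1000 * G)),
        Kallisto_MapRate=float(rng.uniform(0, 1)),
        Kallisto_MappedReads=float(rng.uniform(0, 1000 * G)),
        DatasetCorrel=None if rng.random() < 0.1 else float(rng.uniform(-1, 1)),
        n_genes=G,
    )


def test_agrees_with_brute_force_on_random_metrics():
    rng = np.random.default_rng(424242)
    for _ in range(10_000):
        m = random_metrics(rng)
        c = qc.classify(m)
        status, levels = brute_force_classify(m)
        assert (c.status, c.levels) == (status, levels)


def test_improving_a_metric_never_worsens_status():
    order = {"fail": 0, "warn": 1, "pass": 2}
    rng = np.random.default_rng(7)
    rate_fields = ["QcPassRate", "STAR_UniqMapRate", "STAR_AssignRate", "Kallisto_MapRate"]
    count_fields = ["NumReadsQcPass", "STAR_AssignedReads", "Kallisto_MappedReads"]
    for _ in range(300):
        m = random_metrics(rng)
        before = order[qc.classify(m).status]
        field = str(rng.choice(rate_fields + count_fields + ["DatasetCorrel"]))
        better = dict(m.__dict__)
        if field in rate_fields:
            better[field] = min(1.0, m.__dict__[field] + rng.uniform(0, 0.5))
        elif field == "DatasetCorrel":
            if m.DatasetCorrel is None:
                continue
            better[field] = min(1.0, m.DatasetCorrel + rng.uniform(0, 1))
        else:
            better[field] = m.__dict__[field] + int(rng.integers(0, 100 * m.n_genes))
        after = order[qc.classify(qc.QcMetricSet(**better)).status]
        assert after >= before


class TestPassAverage:
    def _matrix(self, cols: dict[str, list[float]]) -> ExpressionMatrix:
        return ExpressionMatrix(
            pd.DataFrame(cols, index=[f"g{i}" for i in range(len(next(iter(cols.values()))))]),
            "gene")

    def test_identical_pass_runs_give_their_profile(self):
        m = self._matrix({"a": [10, 30], "b": [20, 60], "c": [1, 3]})
        cls = {r: qc.QcClassification("pass") for r in "abc"}
        avg = qc.build_pass_average(m, cls)
        assert avg.n_runs == 3
        np.testing.assert_allclose(avg.profile.to_numpy(), [2.5e5, 7.5e5])

    def test_failing_run_excluded(self):
        m = self._matrix({"a": [10, 0], "b": [0, 10]})
        cls = {"a": qc.QcClassification("pass"),
               "b": qc.QcClassification("fail", {3}, {3: "fail"})}
        avg = qc.build_pass_average(m, cls)
        assert avg.n_runs == 1
        np.testing.assert_allclose(avg.profile.to_numpy(), [1e6, 0.0])

    def test_rule8_only_warn_still_eligible(self):
        m = self._matrix({"a": [10, 0], "b": [0, 10]})
        cls = {"a": qc.QcClassification("warn", {8}, {8: "warn"}),
               "b": qc.QcClassification("pass")}
        assert qc.build_pass_average(m, cls).n_runs == 2

    def test_mean_of_two_orthogonal_runs(self):
        m = self._matrix({"a": [10, 0], "b": [0, 10]})
        cls = {r: qc.QcClassification("pass") for r in "ab"}
        np.testing.assert_allclose(qc.build_pass_average(m, cls).profile.to_numpy(),
                                   [5e5, 5e5])

    def test_no_eligible_runs_errors(self):
        m = self._matrix({"a": [1, 2]})
        cls = {"a": qc.QcClassification("fail", {1}, {1: "fail"})}
        with pytest.raises(ValueError, match="pass"):
            qc.build_pass_average(m, cls)

    def test_subsampling_deterministic(self):
        rng = np.random.default_rng(3)
        cols = {f"r{i}": rng.integers(1, 100, size=20).tolist() for i in range(30)}
        m = self._matrix(cols)
        cls = {r: qc.QcClassification("pass") for r in cols}
        a = qc.build_pass_average(m, cls, max_runs=10, rng_seed=5)
        b = qc.build_pass_average(m, cls, max_runs=10, rng_seed=5)
        pd.testing.assert_series_equal(a.profile, b.profile)


class TestDatasetCorrel:
    def test_identical_run_scores_one(self):
        counts = pd.Series([5.0, 10, 20, 40], index=list("abcd"))
        avg = qc.PassAverageProfile(counts * 1e6 / counts.sum(), 1)
        assert qc.dataset_correl(counts, avg) == 1.0

    def test_scale_invariance(self):
        counts = pd.Series([5.0, 10, 20, 40], index=list("abcd"))
        avg = qc.PassAverageProfile(pd.Series([1.0, 4, 2, 9], index=list("abcd")), 1)
        assert qc.dataset_correl(counts, avg) == qc.dataset_correl(counts * 7, avg)

    def test_anticorrelated_scores_minus_one(self):
        counts = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        avg = qc.PassAverageProfile(pd.Series([4.0, 3, 2, 1], index=list("abcd")), 1)
        assert qc.dataset_correl(counts, avg) == -1.0

    def test_two_sigfig_rounding_against_high_precision_oracle(self):
        rng = np.random.default_rng(12)
        x = pd.Series(rng.uniform(1, 100, 50), index=[f"g{i}" for i in range(50)])
        y = x + rng.normal(0, 40, 50).clip(-0.9 * x)
        avg = qc.PassAverageProfile(y, 1)
        r = float(np.corrcoef(x * 1e6 / x.sum(), y)[0, 1])
        expected = round(r, 1 - math.floor(math.log10(abs(r))))
        assert qc.dataset_correl(x, avg) == expected

    def test_zero_variance_returns_na(self):
        counts = pd.Series([3.0, 3, 3, 3], index=list("abcd"))
        avg = qc.PassAverageProfile(pd.Series([1.0, 2, 3, 4], index=list("abcd")), 1)
        assert qc.dataset_correl(counts, avg) is None


@pytest.mark.parametrize("x,expected", [
    (0.4936, 0.49), (0.501, 0.5), (-0.4936, -0.49), (0.999, 1.0),
    (0.0, 0.0), (0.045, 0.045)])
def test_round_sigfigs(x, expected):
    assert qc.round_sigfigs(x, 2) == pytest.approx(expected)
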