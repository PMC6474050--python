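import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pairprot as pp
from pairprot import CodeTag, Direction, PairedCode
from pairprot.paired import _z_from_p

from conftest import WORKED_CODES, make_dataset


def codes_from_symbols(symbols):
    """Turn the compact per-subject notation into PairedCode objects."""
    out = {}
    for i, s in enumerate(symbols):
        key = f"S{i + 1:02d}"
        if s is None:
            out[key] = PairedCode.absent()
        elif s == "+":
            out[key] = PairedCode.case_only()
        elif s == "-":
            out[key] = PairedCode.control_only()
        else:
            out[key] = PairedCode.ratio(s)
    return out


class TestCodeSubject:
    @pytest.mark.parametrize(
        "case, control, tag, value",
        [
            (0.19, 1.0, CodeTag.RATIO, 0.19),
            (5.0, 10.0, CodeTag.RATIO, 0.5),
            (None, None, CodeTag.ABSENT, None),
            (0.0, 0.0, CodeTag.ABSENT, None),  # zero area means "not obtained"
            (5.0, None, CodeTag.CASE_ONLY, None),
            (5.0, 0.0, CodeTag.CASE_ONLY, None),
            (None, 3.0, CodeTag.CONTROL_ONLY, None),
        ],
    )
    def test_four_state_coding(self, case, control, tag, value):
        code = pp.code_subject(case, control)
        assert code.tag is tag
        if value is not None:
            assert code.value == pytest.approx(value)

    def test_success_definition(self):
        assert pp.code_subject(2.0, 1.0).is_success
        assert pp.code_subject(5.0, None).is_success
        assert not pp.code_subject(1.0, 1.0).is_success  # ratio exactly 1 is a failure
        assert not pp.code_subject(None, 5.0).is_success


class TestBinomialPeptide:
    @pytest.mark.parametrize(
        "peptide, x, n, p",
        [
            ("LVNEVTEFAK", 3, 5, 0.5),
            ("YLYEIAR", 2, 10, 0.9892578125),
            ("AEFAEVSK", 6, 6, 0.015625),
        ],
    )
    def test_worked_example_rows(self, peptide, x, n, p):
        stat = pp.peptide_pvalue(codes_from_symbols(WORKED_CODES[peptide]), peptide)
        assert (stat.x, stat.n) == (x, n)
        assert stat.p_value == pytest.approx(p, abs=1e-15)

    def test_worked_example_avg_log2_folds(self):
        folds = {
            pep: pp.avg_log2_fold(codes_from_symbols(sym)) for pep, sym in WORKED_CODES.items()
        }
        assert folds["LVNEVTEFAK"] == pytest.approx(-0.36, abs=5e-3)
        assert folds["AEFAEVSK"] == pytest.approx(1.67, abs=5e-3)
        assert folds["YLYEIAR"] == pytest.approx(-1.53, abs=0.03)

    def test_single_trial(self):
        stat = pp.peptide_pvalue({"S1": PairedCode.ratio(2.0)})
        assert (stat.x, stat.n, stat.p_value) == (1, 1, 0.5)

    def test_all_absent_raises(self):
        with pytest.raises(ValueError, match="n=0"):
            pp.peptide_pvalue({"S1": PairedCode.absent()})

    def test_avg_fold_edge_cases(self):
        assert pp.avg_log2_fold({"S1": PairedCode.ratio(2.0)}) == pytest.approx(1.0)
        assert math.isnan(pp.avg_log2_fold({"S1": PairedCode.case_only()}))

    def test_monotonicity_in_successes(self):
        """Adding one success (n -> n+1 trials) never increases the p-value."""
        for n in range(1, 21):
            for x in range(n + 1):
                assert pp.binom_tail_p(x + 1, n + 1) <= pp.binom_tail_p(x, n) + 1e-15

    @given(
        st.lists(
            st.one_of(
                st.just("+"),
                st.just("-"),
                st.floats(0.01, 100.0).filter(lambda r: abs(r - 1.0) > 1e-6),
            ),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_case_control_antisymmetry(self, symbols):
        """Swapping the case/control labels mirrors the statistic exactly.

        Ratios invert, '+' and '-' swap, so x -> n - x and the inclusive
        tail obeys p' = 1 - p + P(X = x); significance directions swap.
        """
        codes = codes_from_symbols(symbols)
        swapped = {}
        for k, c in codes.items():
            if c.tag is CodeTag.RATIO:
                swapped[k] = PairedCode.ratio(1.0 / c.value)
            elif c.tag is CodeTag.CASE_ONLY:
                swapped[k] = PairedCode.control_only()
            else:
                swapped[k] = PairedCode.case_only()
        a = pp.peptide_pvalue(codes)
        b = pp.peptide_pvalue(swapped)
        assert b.n == a.n and b.x == a.n - a.x
        point_mass = math.comb(a.n, a.x) / 2**a.n
        assert b.p_value == pytest.approx(1.0 - a.p_value + point_mass, abs=1e-12)
        # a case call always mirrors to a control call; the converse does not
        # hold exactly because the inclusive tail carries the point mass P(X=x)
        if pp.classify(a.p_value) is Direction.CASE_UP:
            assert pp.classify(b.p_value) is Direction.CONTROL_UP
        if pp.classify(b.p_value) is Direction.CASE_UP:
            assert pp.classify(a.p_value) is Direction.CONTROL_UP


class TestStouffer:
    @pytest.mark.parametrize("x, n", [(3, 5), (6, 6), (2, 10), (0, 4)])
    def test_single_peptide_identity(self, x, n):
        """With k=1 the protein p-value equals the peptide p-value through Phi."""
        pep = pp.PeptideStat(peptide="A", x=x, n=n, p_value=pp.binom_tail_p(x, n))
        prot = pp.stouffer_protein([pep], "P1")
        assert prot.p_value == pytest.approx(pep.p_value, abs=1e-12)
        assert prot.weights == [math.sqrt(n)]

    def test_duplicate_peptides_scale_z_by_sqrt_k(self):
        pep = pp.PeptideStat(peptide="A", x=5, n=6, p_value=pp.binom_tail_p(5, 6))
        z1 = pp.stouffer_protein([pep], "P1").z
        for k in (2, 3, 5):
            zk = pp.stouffer_protein([pep] * k, "P1").z
            assert zk == pytest.approx(math.sqrt(k) * z1, rel=1e-12)

    def test_two_equal_peptides_sharpen_p(self):
        pep = pp.PeptideStat(peptide="A", x=5, n=6, p_value=pp.binom_tail_p(5, 6))
        prot = pp.stouffer_protein([pep, pep], "P1")
        assert prot.z == pytest.approx(math.sqrt(2) * _z_from_p(pep.p_value), rel=1e-12)
        assert prot.p_value < pep.p_value < 0.5

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=8)
        w = rng.uniform(0.5, 3.0, size=8)
        base = pp.stouffer_combine(z, w)
        for c in (0.1, 2.0, 1e3):
            assert pp.stouffer_combine(z, c * w) == pytest.approx(base, rel=1e-12)

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            pp.stouffer_protein([], "P1")
        with pytest.raises(ValueError):
            pp.stouffer_combine([], [])

    def test_extreme_p_clamped_finite(self):
        pep = pp.PeptideStat(peptide="A", x=0, n=3, p_value=1.0)
        prot = pp.stouffer_protein([pep], "P1")
        assert math.isfinite(prot.z) and prot.direction is Direction.CONTROL_UP


class TestClassify:
    @pytest.mark.parametrize(
        "p, direction",
        [
            (0.0156, Direction.CASE_UP),
            (0.025, Direction.NOT_SIGNIFICANT),  # thresholds are strict
            (0.5, Direction.NOT_SIGNIFICANT),
            (0.975, Direction.NOT_SIGNIFICANT),
            (0.9998, Direction.CONTROL_UP),
        ],
    )
    def test_thresholds(self, p, direction):
        assert pp.classify(p) is direction

    def test_invalid_alphas(self):
        with pytest.raises(ValueError):
            pp.classify(0.5, alpha_low=0.9, alpha_high=0.1)


class TestBatchConsistency:
    def test_analyze_dataset_matches_scalar_path(self):
        """The vectorized analysis agrees with the one-peptide/one-protein API."""
        cfg = pp.preset("homogeneous", n_proteins=15, seed=3)
        ds, _ = pp.simulate(cfg)
        ds = pp.filter_proteotypic(pp.filter_sequential_points(pp.normalize_tic(ds)))
        result = pp.analyze_dataset(ds)
        coded = pp.code_peptides(ds)
        for _, row in result.peptides.iterrows():
            sub = coded[coded["peptide"] == row["peptide"]]
            codes = {
                r["subject"]: pp.code_subject(r["case_area"], r["control_area"])
                for _, r in sub.iterrows()
            }
            stat = pp.peptide_pvalue(codes, row["peptide"])
            assert (stat.x, stat.n) == (row["x"], row["n"])
            assert stat.p_value == pytest.approx(row["p_value"], abs=1e-12)
            if math.isnan(stat.avg_log2_fold):
                assert math.isnan(row["avg_log2_fold"])
            else:
                assert stat.avg_log2_fold == pytest.approx(row["avg_log2_fold"], abs=1e-12)
        # protein roll-up agreement
        pep_by_acc = result.peptides.groupby("accession")
        for _, prow in result.proteins.iterrows():
            peps = pep_by_acc.get_group(prow["accession"])
            stats = [
                pp.PeptideStat(peptide=r["peptide"], x=r["x"], n=r["n"], p_value=r["p_value"])
                for _, r in peps.iterrows()
            ]
            prot = pp.stouffer_protein(stats, prow["accession"])
            assert prot.z == pytest.approx(prow["z"], abs=1e-12)
            assert prot.p_value == pytest.approx(prow["p_value"], abs=1e-12)
            assert prot.direction.value == prow["direction"]


class TestCrossCohortExclude:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["accession", "p_value", "direction"])

    def test_exclusion_rule(self):
        case = self._frame(
            [
                ("A", 0.001, "case_up"),
                ("B", 0.002, "case_up"),
                ("C", 0.5, "not_significant"),
            ]
        )
        control = self._frame([("A", 0.99, "control_up"), ("C", 0.4, "not_significant")])
        filtered, removed = pp.cross_cohort_exclude(case, control)
        assert removed["accession"].tolist() == ["A"]  # significant in both
        assert filtered["accession"].tolist() == ["B", "C"]

    def test_empty_control_is_identity(self):
        case = self._frame([("A", 0.001, "case_up")])
        filtered, removed = pp.cross_cohort_exclude(case, case.iloc[0:0])
        assert filtered["accession"].tolist() == ["A"] and len(removed) == 0


class TestNiaf:
    def test_single_protein_is_one(self):
        ds = make_dataset([{"peptide": "A", "proteins": ("P1",), "xic_area": 5.0}])
        out = pp.niaf(pp.normalize_tic(ds))
        assert out["mean_niaf"].tolist() == [1.0]

    def test_equal_split_and_scale_invariance(self):
        rows = [
            {"peptide": "A", "proteins": ("P1",), "xic_area": 3.0},
            {"peptide": "B", "proteins": ("P2",), "xic_area": 3.0},
        ]
        out1 = pp.niaf(pp.normalize_tic(make_dataset(rows)))
        assert out1["mean_niaf"].tolist() == [0.5, 0.5]
        doubled = [{**r, "xic_area": 2 * r["xic_area"]} for r in rows]
        out2 = pp.niaf(pp.normalize_tic(make_dataset(doubled)))
        pd.testing.assert_series_equal(out1["mean_niaf"], out2["mean_niaf"])

    def test_sums_to_one_and_ranked(self):
        cfg = pp.preset("homogeneous", n_proteins=20, seed=1)
        ds, _ = pp.simulate(cfg)
        out = pp.niaf(pp.normalize_tic(ds))
        # shares averaged over samples still sum to 1 when every sample saw every protein
        assert out["mean_niaf"].sum() == pytest.approx(1.0, abs=1e-6)
        assert out["rank"].tolist() == list(range(1, len(out) + 1))
        assert out["mean_niaf"].is_monotonic_decreasing
        assert (out["neg_log_score"] > 0).all()


class TestBaselineUnpaired:
    def _paired_rows(self, deltas):
        rows = []
        for i, d in enumerate(deltas):
            subj = f"S{i}"
            rows.append({"peptide": "A", "subject": subj, "condition": "case", "xic_area": 2.0**d})
            rows.append({"peptide": "A", "subject": subj, "condition": "control", "xic_area": 1.0})
        return rows

    def test_identical_groups_not_flagged(self):
        out = pp.baseline_unpaired(make_dataset(self._paired_rows([0, 0, 0, 0])))
        assert not out["flagged"].any()
        assert out["t_p"].iloc[0] == pytest.approx(1.0)

    def test_constant_fourfold_shift_flagged(self):
        rows = []
        for i in range(6):
            jitter = 0.05 * i
            rows += [
                {"peptide": "A", "subject": f"S{i}", "condition": "case", "xic_area": 4.0 * (1 + jitter)},
                {"peptide": "A", "subject": f"S{i}", "condition": "control", "xic_area": 1.0 * (1 + jitter)},
            ]
        out = pp.baseline_unpaired(make_dataset(rows), fold_cutoff=1.5, alpha=0.05)
        assert out["flagged"].all()
        assert out["mean_log2_fold"].iloc[0] == pytest.approx(2.0, abs=0.01)

    def test_insufficient_replicates_untestable(self):
        rows = [
            {"peptide": "A", "subject": "S1", "condition": "case", "xic_area": 2.0},
            {"peptide": "A", "subject": "S1", "condition": "control", "xic_area": 1.0},
        ]
        out = pp.baseline_unpaired(make_dataset(rows))
        assert not out["testable"].iloc[0]
        assert not out["flagged"].iloc[0]
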