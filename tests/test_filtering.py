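"""Variant- and gene-level filter cascade."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from chdpath import filtering


class TestHardFilters:
    @pytest.mark.parametrize(
        "overrides, passes",
        [
            ({}, True),  # 40/12 proband (30%), clean parents, AF 0
            ({"pb_tot": 36, "pb_alt": 9}, False),  # 25% < 28% for <10 alt
            ({"pb_tot": 36, "pb_alt": 11}, True),  # 30.6% >= 20% at >=10 alt
            ({"f_altratio": 0.04}, False),  # parental contamination
            ({"m_ref": 8}, False),  # parental depth
            ({"cohort_af": 5e-4}, False),  # in-cohort AF above 4e-4
            ({"cohort_af": 4e-4}, True),  # boundary inclusive
            ({"pb_tot": 9, "pb_alt": 5}, False),  # proband depth
            ({"pb_alt": 4, "pb_tot": 10}, False),  # alt reads below 5
        ],
    )
    def test_printed_thresholds(self, dnv_table, overrides, passes):
        out = filtering.apply_hard_filters(dnv_table([overrides]))
        assert len(out) == (1 if passes else 0)

    def test_missing_read_support_rejected_with_reason(self, dnv_table):
        df = dnv_table([{"pb_tot": np.nan}])
        df["pb_tot"] = pd.array([pd.NA], dtype="Int64")
        kept, dropped = filtering.apply_hard_filters(df, return_dropped=True)
        assert len(kept) == 0
        assert list(dropped["reason"]) == ["missing_field"]


class TestMolecularClass:
    def test_split(self, dnv_table):
        df = dnv_table([{"mol_class": c} for c in
                        ("missense", "synonymous", "frameshift")])
        damaging, syn = filtering.filter_molecular_class(df)
        assert sorted(damaging["mol_class"]) == ["frameshift", "missense"]
        assert list(syn["mol_class"]) == ["synonymous"]

    def test_all_synonymous_gives_empty_damaging(self, dnv_table):
        df = dnv_table([{"mol_class": "synonymous"}] * 3)
        damaging, syn = filtering.filter_molecular_class(df)
        assert damaging.empty and len(syn) == 3

    def test_unknown_label_raises(self, dnv_table):
        df = dnv_table([{"mol_class": "intronic"}])
        with pytest.raises(ValueError, match="intronic"):
            filtering.filter_molecular_class(df)


class TestPopulationMaf:
    def test_rare_in_one_db_absent_elsewhere_kept(self, dnv_table):
        df = dnv_table([{"maf_exac": 5e-4}])
        assert len(filtering.filter_population_maf(df)) == 1

    def test_common_in_any_db_dropped(self, dnv_table):
        df = dnv_table([{"maf_exac": 5e-4, "maf_gnomad": 2e-3}])
        assert len(filtering.filter_population_maf(df)) == 0

    def test_absent_everywhere_kept_by_default_dropped_in_strict(
            self, dnv_table):
        df = dnv_table([{}])
        assert len(filtering.filter_population_maf(df)) == 1
        assert len(filtering.filter_population_maf(df, strict=True)) == 0

    def test_negative_maf_raises(self, dnv_table):
        with pytest.raises(ValueError):
            filtering.filter_population_maf(dnv_table([{"maf_esp": -0.1}]))


@pytest.fixture()
def annotations():
    return pd.DataFrame({
        "gene": ["GENE1", "GENE2", "GENE3"],
        "gdi_class": ["low", "medium", "high"],
        "msc": [3.313, 10.0, 5.0],
        "heart_expr_percentile": [90.0, 50.0, 10.0],
        "known_chd_human": [True, False, False],
        "known_chd_mouse": [False, False, False],
        "tissue_class": ["all_mixed"] * 3,
    })


class TestGeneLevelFilters:
    def test_gdi_drops_high_keeps_low_medium(self, dnv_table, annotations):
        df = dnv_table([{"gene": g} for g in ("GENE1", "GENE2", "GENE3")])
        out = filtering.filter_gdi(df, annotations)
        assert sorted(out["gene"]) == ["GENE1", "GENE2"]

    def test_gdi_empty_input(self, dnv_table, annotations):
        out = filtering.filter_gdi(dnv_table([]), annotations)
        assert out.empty

    def test_unannotated_gene_strict_error(self, dnv_table, annotations):
        df = dnv_table([{"gene": "NOVEL"}])
        with pytest.raises(filtering.UnannotatedGeneError):
            filtering.filter_gdi(df, annotations)
        out = filtering.filter_gdi(df, annotations, on_missing="warn")
        assert len(out) == 1

    @pytest.mark.parametrize("cadd, kept", [
        (25.0, True), (1.0, False), (3.313, True)])  # boundary inclusive
    def test_cadd_msc(self, dnv_table, annotations, cadd, kept):
        df = dnv_table([{"cadd": cadd}])
        out = filtering.filter_cadd_msc(df, annotations)
        assert len(out) == (1 if kept else 0)


class TestXLinkedRecessive:
    def test_rule_table(self, dnv_table):
        rows = [
            {"chrom": "1", "sex": "male", "pb_tot": 40, "pb_alt": 38},
            {"chrom": "X", "sex": "male", "pb_tot": 40, "pb_alt": 36,
             "pos": 50_000_000},
            {"chrom": "X", "sex": "male", "pb_tot": 40, "pb_alt": 18,
             "pos": 50_000_000},
            {"chrom": "X", "sex": "female", "pb_tot": 40, "pb_alt": 38,
             "pos": 50_000_000},
            # male hemizygous-consistent inside PAR1 is kept
            {"chrom": "X", "sex": "male", "pb_tot": 40, "pb_alt": 38,
             "pos": 100_000},
        ]
        df = dnv_table(rows)
        out = filtering.exclude_x_linked_recessive(df)
        # only the male hemizygous non-PAR X record is dropped
        assert len(out) == 4
        dropped = set(df.index) - set(out.index)
        assert df.loc[list(dropped)].iloc[0]["pb_alt"] == 36


def _fisher_two_sided_oracle(a, b, c, d):
    """Exact two-sided Fisher p by enumerating the hypergeometric support."""
    row1, col1, N = a + b, a + c, a + b + c + d

    def pmf(k):
        return Fraction(comb(col1, k) * comb(N - col1, row1 - k),
                        comb(N, row1))

    support = range(max(0, row1 + col1 - N), min(row1, col1) + 1)
    p_obs = pmf(a)
    return float(sum(pmf(k) for k in support if pmf(k) <= p_obs))


class TestSelectGenes:
    def make_records(self, counts, cohort_sizes=None):
        genes = [g for g, n in counts.items() for _ in range(n)]
        return pd.DataFrame({"gene": genes})

    def test_strategy_d_margin(self):
        case = self.make_records({"A": 3, "B": 2})
        ctrl = self.make_records({"A": 1, "B": 1})
        out = filtering.select_genes(case, ctrl, "d", margin=2)
        sel = dict(zip(out["gene"], out["selected"]))
        assert sel == {"A": True, "B": False}

    def test_strategy_c_requires_zero_controls(self):
        case = self.make_records({"A": 1, "B": 2})
        ctrl = self.make_records({"B": 1})
        out = filtering.select_genes(case, ctrl, "c")
        sel = dict(zip(out["gene"], out["selected"]))
        assert sel == {"A": True, "B": False}

    def test_fisher_matches_exact_enumeration(self):
        # 5 case / 0 control in the gene; 315 case / 73 control elsewhere
        case = self.make_records({"X": 5, "REST": 315})
        ctrl = self.make_records({"REST": 73})
        out = filtering.select_genes(case, ctrl, "a")
        p = float(out.loc[out["gene"] == "X", "p_raw"].iloc[0])
        assert p == pytest.approx(
            _fisher_two_sided_oracle(5, 0, 315, 73), rel=1e-10)

    def test_margin_below_one_rejected(self):
        case = self.make_records({"A": 1})
        with pytest.raises(ValueError):
            filtering.select_genes(case, case, "d", margin=0)

    def test_case_and_control_selections_disjoint(self, cohort):
        dnvs, annotations, _ = cohort
        case = dnvs[dnvs["cohort"] == "case"]
        ctrl = dnvs[dnvs["cohort"] == "control"]
        fwd = filtering.select_genes(case, ctrl, "d", 2)
        rev = filtering.select_genes(ctrl, case, "d", 2)
        a = set(fwd.loc[fwd["selected"], "gene"])
        b = set(rev.loc[rev["selected"], "gene"])
        assert a and b and not (a & b)


class TestExtendControlSet:
    def make_burden(self, genes, n_cases, n_controls):
        return pd.DataFrame({
            "gene": genes,
            "n_cases": n_cases,
            "n_controls": n_controls,
        })

    def test_printed_sizes(self):
        base = self.make_burden([f"C{i}" for i in range(36)], 0, 2)
        pool = self.make_burden([f"P{i}" for i in range(769)], 0, 1)
        out = filtering.extend_control_set(base, pool, k=91, seed=3)
        assert len(out) == 127

    def test_k_zero_identity_and_determinism(self):
        base = self.make_burden(["A", "B"], 0, 2)
        pool = self.make_burden([f"P{i}" for i in range(10)], 1, 2)
        assert len(filtering.extend_control_set(base, pool, 0, 1)) == 2
        one = filtering.extend_control_set(base, pool, 4, 9)
        two = filtering.extend_control_set(base, pool, 4, 9)
        pd.testing.assert_frame_equal(one, two)

    def test_pool_validation(self):
        base = self.make_burden(["A"], 0, 2)
        bad_pool = self.make_burden(["P"], 0, 3)
        with pytest.raises(ValueError):
            filtering.extend_control_set(base, bad_pool, 1, 0)
        pool = self.make_burden(["P"], 0, 1)
        with pytest.raises(ValueError):
            filtering.extend_control_set(base, pool, 5, 0)


class TestBlacklist:
    def test_empty_blacklist_is_identity(self, dnv_table):
        df = dnv_table([{}, {"pos": 2}])
        out = filtering.filter_blacklist(df, set())
        pd.testing.assert_frame_equal(out, df)

    def test_planted_record_removed(self, dnv_table):
        df = dnv_table([{}, {"pos": 777, "ref": "C", "alt": "T"}])
        out = filtering.filter_blacklist(df, {("1", 777, "C", "T")})
        assert len(out) == 1
        assert filtering.filter_blacklist(
            df, {("1", 1_000_000, "A", "G"), ("1", 777, "C", "T")}).empty


@pytest.fixture(scope="module")
def filtered_inputs():
    from chdpath import simulate

    cfg = simulate.SimConfig(seed=11, n_genes=300, n_case_trios=80,
                             n_control_trios=60)
    dnvs, annotations, _ = simulate.generate_cohort(cfg)
    damaging, _ = filtering.filter_molecular_class(
        filtering.apply_hard_filters(dnvs))
    return damaging, annotations


class TestCascadeProperties:
    """Record-level filters commute and are idempotent."""

    def test_order_insensitive(self, filtered_inputs):
        damaging, ann = filtered_inputs
        ops = {
            "maf": lambda d: filtering.filter_population_maf(d),
            "gdi": lambda d: filtering.filter_gdi(d, ann),
            "cadd": lambda d: filtering.filter_cadd_msc(d, ann),
            "xlr": filtering.exclude_x_linked_recessive,
        }
        results = set()
        for perm in itertools.permutations(ops.values()):
            df = damaging
            for op in perm:
                df = op(df)
            results.add(tuple(sorted(df.index)))
        assert len(results) == 1

    def test_idempotent(self, filtered_inputs):
        damaging, ann = filtered_inputs
        for op in (
            lambda d: filtering.apply_hard_filters(d),
            lambda d: filtering.filter_population_maf(d),
            lambda d: filtering.filter_gdi(d, ann),
            lambda d: filtering.filter_cadd_msc(d, ann),
            filtering.exclude_x_linked_recessive,
        ):
            once = op(damaging)
            twice = op(once)
            pd.testing.assert_frame_equal(once, twice)
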