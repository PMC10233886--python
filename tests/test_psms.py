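"""Target-decoy FDR, per-assay filtering, peptide mapping, cohort evidence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from crypticorf.psms import (
    NcorfEvidence,
    annotate_differential_expression,
    cohort_pervasiveness,
    compute_fdr,
    filter_psms,
    map_peptides_to_ncorfs,
    read_psm_table,
    stratified_rank_test,
)
from crypticorf.searchdb import ProteinDBEntry, il_collapse


def psm_frame(rows):
    df = pd.DataFrame(
        rows,
        columns=["spectrum_id", "peptide", "score", "probability", "accessions",
                 "sample_id", "cohort", "assay", "is_decoy"],
    )
    return df


def row(sid, score, decoy=False, peptide="PEPTIDEK", prob=0.999, assay="proteome"):
    return (sid, peptide, score, prob, "rev_x" if decoy else "x", "s1", "BRCA", assay, decoy)


class TestComputeFdr:
    def test_no_decoys_all_zero(self):
        df = compute_fdr(psm_frame([row("a", 5), row("b", 4)]))
        assert (df["q_value"] == 0).all()

    def test_hand_counted_example(self):
        """Scores T:10 T:9 D:8 T:7 -> q at score 7 is 1/3."""
        df = compute_fdr(
            psm_frame([row("a", 10), row("b", 9), row("c", 8, decoy=True), row("d", 7)])
        )
        q = df.set_index("spectrum_id")["q_value"]
        assert q["a"] == 0 and q["b"] == 0
        assert q["d"] == pytest.approx(1 / 3)
        # monotonized: the decoy row inherits the downstream minimum
        assert q["c"] == pytest.approx(1 / 3)

    def test_all_decoy_degenerate(self):
        df = compute_fdr(psm_frame([row("a", 5, decoy=True), row("b", 4, decoy=True)]))
        assert (df["q_value"] == 1).all()

    def test_tied_scores_share_one_q(self):
        df = compute_fdr(
            psm_frame([row("a", 3), row("b", 3, decoy=True), row("c", 3), row("d", 3)])
        )
        assert df["q_value"].nunique() == 1

    def test_plus_one_switch_is_more_conservative(self):
        rows = [row(f"t{i}", 10 - i * 0.1) for i in range(20)] + [
            row(f"d{i}", 5 - i * 0.1, decoy=True) for i in range(5)
        ]
        q0 = compute_fdr(psm_frame(rows))["q_value"]
        q1 = compute_fdr(psm_frame(rows), plus_one=True)["q_value"]
        assert (q1 >= q0).all()

    @given(st.lists(st.tuples(st.floats(-3, 8), st.booleans()), min_size=5, max_size=80))
    def test_q_monotone_in_rank(self, pairs):
        rows = [row(f"s{i:03d}", sc, decoy=d) for i, (sc, d) in enumerate(pairs)]
        df = compute_fdr(psm_frame(rows))
        ordered = df.sort_values(["score", "spectrum_id"], ascending=[False, True])
        q = ordered["q_value"].to_numpy()
        assert (np.diff(q) >= -1e-12).all()

    def test_smaller_qmax_never_retains_more(self):
        rng = np.random.default_rng(11)
        rows = [
            row(f"s{i:04d}", float(rng.normal(2 if i % 3 else 0, 1)), decoy=(i % 5 == 0))
            for i in range(300)
        ]
        df = compute_fdr(psm_frame(rows))
        kept_strict = filter_psms(df, q_max=0.01)
        kept_loose = filter_psms(df, q_max=0.05)
        assert set(kept_strict["spectrum_id"]) <= set(kept_loose["spectrum_id"])


class TestFilterPsms:
    def base(self):
        rows = [
            row("keep_imm", 5, peptide="ACDEFGHIK", prob=0.995, assay="immunopeptidome"),
            row("long_imm", 5, peptide="A" * 26, prob=0.999, assay="immunopeptidome"),
            row("low_prob", 5, peptide="ACDEFGHIK", prob=0.98, assay="immunopeptidome"),
            row("prot_hi", 10, assay="proteome"),
            row("decoy", 9, decoy=True),
        ]
        return compute_fdr(psm_frame(rows))

    def test_immunopeptidome_thresholds(self):
        kept = set(filter_psms(self.base())["spectrum_id"])
        assert "keep_imm" in kept
        assert "long_imm" not in kept      # length 26 > 25
        assert "low_prob" not in kept      # probability below 0.99
        assert "decoy" not in kept

    def test_proteome_q_boundary(self):
        # force a q of exactly 0.011 via a crafted decoy/target layout:
        # 89 targets above, then 1 decoy, then 2 more targets -> 1/91 ~ 0.011
        rows = [row(f"t{i:03d}", 100 - i) for i in range(89)]
        rows.append(row("d1", 5, decoy=True))
        rows += [row("t_last1", 4), row("t_last2", 3)]
        df = compute_fdr(psm_frame(rows))
        q_last = df.set_index("spectrum_id").loc["t_last2", "q_value"]
        assert q_last == pytest.approx(1 / 91)
        kept = set(filter_psms(df, q_max=0.01)["spectrum_id"])
        assert "t_last2" not in kept and "t000" in kept

    def test_validated_column_respected(self):
        df = self.base()
        df["validated"] = [True, True, True, False, True]
        kept = set(filter_psms(df)["spectrum_id"])
        assert "prot_hi" not in kept


class TestMapping:
    DB = [
        ProteinDBEntry("ncorf|orfA|uORF_5utr", "MAAAWDDKCCHK", "ncorf"),
        ProteinDBEntry("ncorf|orfB|ncRNA", "MWWWTTTKDDDK", "ncorf"),
        ProteinDBEntry("sp|g1|t1", "AAKVIGLAAK", "canonical"),
    ]

    def frame(self, peptides, cohorts=None):
        cohorts = cohorts or ["BRCA"] * len(peptides)
        rows = [
            (f"s{i}", p, 5.0, 0.999, "x", f"{c}-S0", c, "proteome", False)
            for i, (p, c) in enumerate(zip(peptides, cohorts))
        ]
        df = compute_fdr(psm_frame(rows))
        return filter_psms(df)

    def test_unique_peptide_maps_to_one_orf(self):
        ev, report = map_peptides_to_ncorfs(self.frame(["AAAWDDK"]), self.DB)
        assert set(ev) == {"orfA"}
        assert ev["orfA"].peptides == {"AAAWDDK"}
        assert report["discarded_canonical"] == []

    def test_canonical_il_equivalent_discarded(self):
        """KVLGL matches canonical ...KVIGL... under I=L and is discarded."""
        ev, report = map_peptides_to_ncorfs(self.frame(["KVLGL"]), self.DB)
        assert ev == {}
        assert report["discarded_canonical"] == ["KVLGL"]

    def test_orphan_reported_not_raised(self):
        ev, report = map_peptides_to_ncorfs(self.frame(["MNOPQRST".replace("O", "N")]), self.DB)
        assert report["orphan"] != []

    def test_planted_peptides_recover_planted_orfs(self, study):
        """Ground-truth recovery: every supported ORF's peptides occur in its
        protein, and all retained mapped peptides avoid canonical space."""
        orf_by_id = {o.orf_id: o for o in study.orfs}
        canon_il = [il_collapse(e.sequence) for e in study.reference.canonical]
        assert study.evidence, "expected nonempty evidence"
        for ev in study.evidence.values():
            prot = il_collapse(orf_by_id[ev.orf_id].protein)
            for pep in ev.peptides:
                assert il_collapse(pep) in prot
                assert not any(il_collapse(pep) in c for c in canon_il)


class TestCohortEvidence:
    def ev(self, orf_id, n):
        return NcorfEvidence(
            orf_id=orf_id,
            peptides={"PEPK"},
            cohorts_supported={f"c{i}" for i in range(n)},
            assay_support={"proteome"},
        )

    def test_pervasiveness_boundary(self):
        evidence = {"a": self.ev("a", 8), "b": self.ev("b", 7)}
        assert cohort_pervasiveness(evidence, 8) == ["a"]

    def test_pervasiveness_monotone_in_threshold(self):
        evidence = {f"o{n}": self.ev(f"o{n}", n) for n in range(1, 11)}
        prev = None
        for k in range(1, 12):
            flagged = set(cohort_pervasiveness(evidence, k))
            if prev is not None:
                assert flagged <= prev
            prev = flagged

    @pytest.mark.parametrize(
        "lfc,p,expected",
        [(1.6, 0.005, "over"), (-1.5, 0.005, "under"), (2.0, 0.02, "none"),
         (1.5, 0.005, "over"), (1.4, 0.005, "none")],
    )
    def test_de_thresholds(self, lfc, p, expected):
        evidence = {"a": self.ev("a", 1)}
        de = pd.DataFrame([{"gene_id": "g1", "log2fc": lfc, "pvalue": p}])
        out = annotate_differential_expression(evidence, {"a": "g1"}, de)
        assert out["a"] == expected

    def test_gene_absent_is_none(self):
        evidence = {"a": self.ev("a", 1)}
        de = pd.DataFrame([{"gene_id": "gX", "log2fc": 3.0, "pvalue": 1e-5}])
        assert annotate_differential_expression(evidence, {"a": "g1"}, de)["a"] == "none"


class TestRankTest:
    def test_identical_groups_p_near_one(self):
        stat, p = stratified_rank_test([1, 2, 3], [1, 2, 3])
        assert p > 0.6

    def test_complete_separation_exact_p(self):
        """{1,2,3} vs {10,11,12}: minimal U statistic, exact two-sided
        p = 2/C(6,3) = 0.1."""
        stat, p = stratified_rank_test([1, 2, 3], [10, 11, 12])
        assert stat == 0.0
        assert p == pytest.approx(0.1)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            stratified_rank_test([], [1.0])

    def test_shift_alternative_power(self):
        """1-SD shift at n=200/group is detected at p<0.001 in >=95% of seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, 200)
            b = rng.normal(1, 1, 200)
            _, p = stratified_rank_test(a, b)
            hits += p < 0.001
        assert hits >= 95


class TestIO:
    def test_read_psm_table_derives_decoy_flag(self, tmp_path, study):
        path = tmp_path / "psms.tsv"
        study.psms.drop(columns=["q_value", "is_decoy"]).to_csv(path, sep="\t", index=False)
        df = read_psm_table(path)
        orig = study.psms.set_index("spectrum_id")["is_decoy"]
        got = df.set_index("spectrum_id")["is_decoy"]
        assert got.sort_index().equals(orig.sort_index())
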