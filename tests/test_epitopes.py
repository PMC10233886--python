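"""Mutated proteomes, wildtype elimination, prioritization cascade."""

import numpy as np
import pytest
from scipy import stats

from crypticorf.epitopes import (
    EpitopeCandidate,
    build_mutated_proteome,
    candidate_peptides,
    eliminate_wildtype_matches,
    hydrophobicity_index,
    prioritize_epitopes,
    retention_time_error,
    RETENTION_COEFFICIENTS,
)
from crypticorf.searchdb import DigestSpec, ProteinDBEntry, il_collapse


class TestMutatedProteome:
    def test_missense_changes_exactly_one_residue(self, study):
        wt_by_orf = {o.orf_id: o.protein for o in study.orfs}
        point = [
            mp
            for mp in study.mutated
            if len(mp.variant_ids) == 1 and len(mp.mut_protein) == len(mp.wt_protein)
        ]
        assert point, "expected at least one single-SNV mutated protein"
        for mp in point:
            diffs = [
                i
                for i, (a, b) in enumerate(zip(mp.wt_protein, mp.mut_protein))
                if a != b
            ]
            assert len(diffs) >= 1
            lo, hi = mp.changed_interval
            assert all(lo <= i < hi for i in diffs)
            assert mp.wt_protein == wt_by_orf[mp.orf_id]

    def test_canonical_missense_over_ncorf_excluded(self, study):
        """Variants altering the canonical protein are not eligible for the
        mutated non-canonical proteome."""
        eligible_keys = {k for mp in study.mutated for k in mp.variant_ids}
        for cell in study.variant_truth.cells:
            if cell["canonical_class"] == "missense":
                assert cell["key"] not in eligible_keys

    def test_frameshift_diverges_to_new_stop(self, study):
        fs = [
            mp
            for mp in study.mutated
            if len(mp.mut_protein) != len(mp.wt_protein)
        ]
        for mp in fs:
            lo, hi = mp.changed_interval
            assert hi == len(mp.mut_protein)
            assert "*" not in mp.mut_protein

    def test_mutated_differs_from_wildtype_everywhere(self, study):
        for mp in study.mutated:
            assert mp.mut_protein != mp.wt_protein


class TestWildtypeElimination:
    def test_peptide_identical_to_wildtype_removed(self, study):
        mp = study.mutated[0]
        wt_db = [ProteinDBEntry("c1", mp.wt_protein, "canonical")]
        # a peptide lifted verbatim from the wildtype protein
        wt_pep = mp.wt_protein[:9]
        fake = [(wt_pep, mp)]
        assert eliminate_wildtype_matches(fake, wt_db) == []

    def test_peptide_covering_change_retained(self):
        from crypticorf.epitopes import MutatedProtein

        mp = MutatedProtein(
            orf_id="o",
            sample_id="s",
            wt_protein="MAAAAKWWWK",
            mut_protein="MAAACKWWWK",
            variant_ids=("v",),
            changed_interval=(4, 5),
        )
        wt_db = [ProteinDBEntry("c1", "MAAAAKWWWK", "canonical")]
        got = eliminate_wildtype_matches([("MAAACK", mp)], wt_db)
        assert got == [("MAAACK", mp)]
        # a peptide missing the changed residue is dropped even if novel
        assert eliminate_wildtype_matches([("WWWK", mp)], wt_db) == []

    def test_exhaustive_no_retained_in_wildtype(self, study):
        """Brute-force scan: no retained neoantigen peptide occurs in any
        wildtype protein under I=L."""
        wildtype = [e for e in study.db if e.origin != "decoy"]
        wt_il = [il_collapse(e.sequence) for e in wildtype]
        assert study.neo_peptides, "expected retained neoantigen peptides"
        for pep, _mp in study.neo_peptides:
            pil = il_collapse(pep)
            assert not any(pil in seq for seq in wt_il)

    def test_retained_span_changed_interval(self, study):
        for pep, mp in study.neo_peptides:
            lo, hi = mp.changed_interval
            start = mp.mut_protein.find(pep)
            found = False
            while start != -1:
                if start < hi and start + len(pep) > lo:
                    found = True
                    break
                start = mp.mut_protein.find(pep, start + 1)
            assert found


class TestRetentionTime:
    @pytest.mark.parametrize(
        "obs,pred,err", [(10.0, 12.5, 2.5), (10.0, 15.0, 5.0), (7.3, 7.3, 0.0)]
    )
    def test_absolute_error(self, obs, pred, err):
        assert retention_time_error(obs, pred) == pytest.approx(err)

    def test_five_minutes_is_a_fail(self):
        c = EpitopeCandidate(
            peptide="ACDK", orf_id="o", sample_id="s", hla_allele="HLA-A*02:01",
            affinity_nM=10.0, rt_observed_min=10.0, rt_predicted_min=15.0,
        )
        _, report = prioritize_epitopes([c])
        assert "rt_pass" not in c.flags and report == []

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            retention_time_error(float("nan"), 1.0)


class TestHydrophobicity:
    def test_all_zero_coefficients_give_zero(self):
        coeffs = {aa: 0.0 for aa in RETENTION_COEFFICIENTS}
        assert hydrophobicity_index("ACDEFGHIK", coeffs) == 0.0

    def test_additivity_monotone(self):
        base = hydrophobicity_index("ACDK")
        assert hydrophobicity_index("ACDKW") == pytest.approx(
            base + RETENTION_COEFFICIENTS["W"]
        )
        assert hydrophobicity_index("ACDKW") > base

    def test_unknown_residue_is_error(self):
        with pytest.raises(ValueError):
            hydrophobicity_index("ACDX")

    def test_self_consistent_rt_correlation(self):
        """RT simulated from the same coefficients correlates r > 0.95."""
        rng = np.random.default_rng(9)
        aas = np.array(list(RETENTION_COEFFICIENTS))
        peptides = [
            "".join(aas[rng.integers(0, 20, int(rng.integers(8, 26)))])
            for _ in range(200)
        ]
        hi = np.array([hydrophobicity_index(p) for p in peptides])
        rt = 0.35 * hi + 18.0 + rng.normal(0, 1.0, len(hi))
        r, _ = stats.pearsonr(hi, rt)
        assert r > 0.95


class TestPrioritization:
    def cand(self, affinity, rt_err=None, tpm=None, mutated=False, pep="ACDEFGHIK"):
        kw = {}
        if rt_err is not None:
            kw.update(rt_observed_min=20.0 + rt_err, rt_predicted_min=20.0)
        return EpitopeCandidate(
            peptide=pep, orf_id="o", sample_id="s", hla_allele="HLA-A*02:01",
            affinity_nM=affinity, gtex_median_tpm=tpm, mutated=mutated, **kw,
        )

    def test_high_affinity_with_rt_reported(self):
        c = self.cand(8.91, rt_err=2.0)
        _, report = prioritize_epitopes([c])
        assert report == [c]
        assert {"affinity_pass", "rt_pass"} <= c.flags

    def test_affinity_gate_is_absolute(self):
        c = self.cand(200.0, rt_err=0.1, tpm=0.1)
        _, report = prioritize_epitopes([c])
        assert report == []

    def test_gtex_route(self):
        c = self.cand(100.0, rt_err=6.0, tpm=0.5)
        _, report = prioritize_epitopes([c])
        assert report == [c]
        assert "gtex_pass" in c.flags and "rt_pass" not in c.flags

    def test_rank_alternative_criterion(self):
        c = self.cand(400.0, rt_err=1.0)
        c.percentile_rank = 1.5
        _, report = prioritize_epitopes([c], rank_max=2.0)
        assert report == [c]

    def test_report_sorted_by_affinity(self):
        cands = [self.cand(a, rt_err=1.0, pep=f"PEP{i}K") for i, a in enumerate([90, 10, 50])]
        _, report = prioritize_epitopes(cands)
        assert [c.affinity_nM for c in report] == [10, 50, 90]

    def test_set_algebra_identity(self, study):
        """Report equals {affinity<=150} & ({rt<5} | {tpm<1}) recomputed
        from the raw values."""
        expected = set()
        for c in study.candidates:
            aff = c.affinity_nM <= 150.0
            rt = c.rt_error_min is not None and c.rt_error_min < 5.0
            gx = c.gtex_median_tpm is not None and c.gtex_median_tpm < 1.0
            if aff and (rt or gx):
                expected.add(id(c))
        assert {id(c) for c in study.report} == expected

    def test_cascade_monotonicity(self, study):
        base = len(study.report)
        for kw in (
            {"affinity_max": 50.0},
            {"rt_max": 2.0},
            {"tpm_max": 0.5},
        ):
            _, tightened = prioritize_epitopes(study.candidates, **kw)
            assert len(tightened) <= base
        # restore baseline flags for other tests
        prioritize_epitopes(study.candidates)

    def test_epitope_vs_neoantigen_labels(self, study):
        for c in study.report:
            assert ("mutated" in c.flags) == c.mutated
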