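"""Clone haplotyping: SNP informativeness, bisulfite alignment, assignment,
methylation matrices and the cis-ASM vs parent-of-origin verdict."""

import numpy as np
import pandas as pd
import pytest

from capemeth.haplotyping import (
    AMBIGUOUS,
    AlleleMethylationMatrix,
    UnalignableCloneError,
    align_clone_bisulfite,
    allele_methylation_matrix,
    assign_clone_allele,
    classify_poe_vs_asm,
    classify_snp_informativeness,
)
from capemeth.pipeline import haplotype_clone_set
from capemeth.simulate import SimulationConfig, build_world, simulate_clones


def defs(*rows):
    return pd.DataFrame(rows, columns=["pos", "P1", "M2", "M3"])


class TestSnpInformativeness:
    def test_g_to_a_fully_informative(self):
        info = classify_snp_informativeness(defs((10, "G", "A", "A")))
        assert info[0].status == "informative"
        assert info[0].pair_status == {("P1", "M2"): True, ("P1", "M3"): True}

    def test_c_vs_t_confounded(self):
        # unmethylated C reads as T: the pair is post-conversion ambiguous
        info = classify_snp_informativeness(defs((10, "C", "T", "T")))
        assert info[0].status == "confounded"

    def test_g_vs_c_informative(self):
        # C observes as {C,T}, disjoint from {G}
        info = classify_snp_informativeness(defs((10, "G", "C", "G")))
        assert info[0].status == "informative"

    def test_partial_informativeness(self):
        # P1/M2 = C vs T (confounded pair), P1/M3 and M2/M3 involve A
        info = classify_snp_informativeness(defs((10, "C", "T", "A")))
        assert info[0].status == "partially_informative"
        assert info[0].pair_status[("P1", "M2")] is False
        assert info[0].pair_status[("P1", "M3")] is True

    def test_minus_strand_complements_logic(self):
        # G/A on the plus strand is C/T on the minus (assayed) strand
        info = classify_snp_informativeness(defs((10, "G", "A", "A")),
                                            assay_strand="-")
        assert info[0].status == "confounded"

    def test_out_of_region_raises(self):
        with pytest.raises(IndexError):
            classify_snp_informativeness(defs((10, "G", "A", "A")),
                                         region_start=1, region_length=5)


class TestAlignment:
    REF = "ACGTACGGTCAGTCGATCGATTGCAGCTA"

    def test_fully_converted_clone_is_identity(self):
        clone = self.REF.replace("C", "T")
        al = align_clone_bisulfite(clone, self.REF)
        assert al.identity == 1.0
        assert "".join(al.bases) == clone

    def test_single_snp_mismatch_recorded(self):
        clone = list(self.REF.replace("C", "T"))
        i = self.REF.index("G")
        clone[i] = "A"
        al = align_clone_bisulfite("".join(clone), self.REF)
        assert al.bases[i] == "A"
        assert al.identity == pytest.approx(1 - 1 / len(self.REF))

    def test_retained_c_is_visible_methylation_candidate(self):
        clone = self.REF.replace("C", "T")
        cg = self.REF.index("CG")
        clone = clone[:cg] + "C" + clone[cg + 1:]
        al = align_clone_bisulfite(clone, self.REF)
        assert al.bases[cg] == "C"  # unconverted = methylated candidate

    def test_gapped_clone_still_aligns(self):
        # drop 2 bases mid-clone: semi-global alignment bridges the gap
        conv = self.REF.replace("C", "T")
        clone = conv[:10] + conv[12:]
        al = align_clone_bisulfite(clone, self.REF)
        covered = sum(b is not None for b in al.bases)
        assert covered >= len(self.REF) - 3
        assert al.identity >= 0.9

    def test_garbage_clone_rejected(self):
        with pytest.raises(UnalignableCloneError):
            align_clone_bisulfite("G" * len(self.REF), self.REF)

    def test_length_bounds(self):
        with pytest.raises(UnalignableCloneError):
            align_clone_bisulfite("ACGT", self.REF)


class TestAssignment:
    REF = "AAGATTTTGAAGATTTTGAA"  # SNP sites at 2 and 12 (0-based)

    def make(self, base1, base2):
        d = defs((3, "G", "A", "A"), (13, "G", "G", "A"))
        info = classify_snp_informativeness(d, region_start=1,
                                            region_length=len(self.REF))
        clone = list(self.REF)
        clone[2], clone[12] = base1, base2
        al = align_clone_bisulfite("".join(clone), self.REF)
        return al, info

    def test_unique_match(self):
        al, info = self.make("G", "G")
        assert assign_clone_allele(al, info) == "P1"
        al, info = self.make("A", "A")
        assert assign_clone_allele(al, info) == "M3"
        al, info = self.make("A", "G")
        assert assign_clone_allele(al, info) == "M2"

    def test_conflict_is_ambiguous(self):
        al, info = self.make("G", "A")  # matches no allele
        assert assign_clone_allele(al, info) == AMBIGUOUS

    def test_min_informative_floor(self):
        al, info = self.make("G", "G")
        assert assign_clone_allele(al, info, min_informative=3) == AMBIGUOUS

    def test_indistinguishable_alleles_tie(self):
        d = defs((3, "G", "A", "A"))  # M2 == M3 at the only SNP
        info = classify_snp_informativeness(d, region_start=1,
                                            region_length=len(self.REF))
        clone = list(self.REF)
        clone[2] = "A"
        al = align_clone_bisulfite("".join(clone), self.REF)
        assert assign_clone_allele(al, info) == AMBIGUOUS


class TestMatrix:
    REF = "TTCGATTTTTCGATTTTTGATT"  # CpGs at 2 and 10; SNP destroys site 10 in M3

    def build(self, clone_bases):
        d = defs((12, "G", "G", "A"))  # 1-based pos 12 = 0-based 11 (the G of CG)
        aligned = {}
        assignments = {}
        for cid, (allele, bases) in clone_bases.items():
            al = align_clone_bisulfite(bases, self.REF)
            aligned[cid] = al
            assignments[cid] = allele
        return allele_methylation_matrix(aligned, assignments, d, self.REF)

    def conv(self, protect=()):
        s = list(self.REF.replace("C", "T"))
        for p in protect:
            s[p] = "C"
        return "".join(s)

    def test_fractions_and_masking(self):
        mat = self.build({
            "c1": ("P1", self.conv(protect=(2, 10))),
            "c2": ("P1", self.conv(protect=(2,))),
            "c3": ("M3", self.conv()),
        })
        f = mat.fraction()
        i_p1 = mat.alleles.index("P1")
        i_m3 = mat.alleles.index("M3")
        j2 = list(mat.site_pos).index(2)
        j10 = list(mat.site_pos).index(10)
        assert f[i_p1, j2] == pytest.approx(1.0)
        assert f[i_p1, j10] == pytest.approx(0.5)
        assert mat.masked[i_m3, j10]          # CpG destroyed on M3 only
        assert not mat.masked[i_p1, j10]
        assert np.isnan(f[i_m3, j10])

    def test_overall_pct_fixed_denominator(self):
        mat = self.build({
            "c1": ("P1", self.conv(protect=(2, 10))),
            "c2": ("P1", self.conv()),
            "c3": ("M3", self.conv(protect=(2,))),
        })
        # P1: 2 methylated calls / (2 possible sites x 2 clones)
        assert mat.overall_pct()["P1"] == pytest.approx(50.0)
        # M3: 1 methylated call / (2 possible x 1 clone) despite 1 masked site
        assert mat.overall_pct()["M3"] == pytest.approx(50.0)

    def test_clone_order_invariance(self):
        clones = {
            "c1": ("P1", self.conv(protect=(2,))),
            "c2": ("M2", self.conv(protect=(10,))),
            "c3": ("M3", self.conv()),
        }
        m1 = self.build(clones)
        m2 = self.build(dict(reversed(list(clones.items()))))
        np.testing.assert_allclose(m1.meth, m2.meth)
        np.testing.assert_allclose(m1.calls, m2.calls)

    def test_all_ambiguous_is_insufficient(self):
        with pytest.raises(ValueError):
            self.build({"c1": (AMBIGUOUS, self.conv())})


class TestVerdict:
    def pooled(self, profile, n=186):
        """profile: allele -> pct; build single-cell pooled matrices."""
        return AlleleMethylationMatrix.from_pooled(
            {a: (round(p / 100 * n), n) for a, p in profile.items()})

    def test_haplotype_profile_is_cis_asm(self):
        # allele-stable profile across modes at 62 calls per cell
        mf = self.pooled({"P1": 51, "M2": 10, "M3": 34}, n=62)
        mt = self.pooled({"P1": 56, "M2": 3, "M3": 28}, n=62)
        v = classify_poe_vs_asm(mf, mt)
        assert v.verdict == "cis_asm"
        assert all(q >= 0.05 for q in v.cross_mode_q.values())
        assert v.heterogeneity_p["fertilized"] < 0.05
        assert v.heterogeneity_p["thelytokous"] < 0.05

    def test_imprinted_profile_is_parent_of_origin(self):
        mf = self.pooled({"P1": 80, "M2": 10, "M3": 10}, n=200)
        mt = self.pooled({"P1": 10, "M2": 10, "M3": 10}, n=200)
        v = classify_poe_vs_asm(mf, mt)
        assert v.verdict == "parent_of_origin"
        assert v.cross_mode_q["P1"] < 0.05
        assert abs(v.delta_pct["P1"]) > abs(v.delta_pct["M2"])

    def test_flat_profile_inconclusive(self):
        mf = self.pooled({"P1": 50, "M2": 50, "M3": 50}, n=100)
        v = classify_poe_vs_asm(mf, mf)
        assert v.verdict == "inconclusive"

    def test_insufficient_data(self):
        mf = self.pooled({"P1": 50, "M2": 50, "M3": 50}, n=20)
        v = classify_poe_vs_asm(mf, mf, min_calls=30)
        assert v.verdict == "insufficient_data"

    def test_mismatched_alleles_raise(self):
        mf = self.pooled({"P1": 50, "M2": 50}, n=100)
        mt = self.pooled({"P1": 50, "M3": 50}, n=100)
        with pytest.raises(ValueError):
            classify_poe_vs_asm(mf, mt)


class TestSimulationRoundTrip:
    def locus(self, regime, seed):
        kw = dict(seed=seed, genome_length=1600, n_genes=1,
                  exons_per_gene=(1, 2), snp_rate=0.01, n_control_sites=0,
                  frac_methylated_genes=0.0, low_meth_level=0.1)
        if regime == "cis":
            kw.update(frac_cis_asm_loci=1.0, low_meth_level=0.05,
                      asm_allele_offsets=(0.45, 0.0, 0.25))
        elif regime == "poe":
            kw.update(frac_imprinted_loci=1.0, imprint_delta=0.7)
        return build_world(SimulationConfig(**kw))

    def test_perfect_conversion_assignment_accuracy(self):
        """With conversion 1.0 every assignable clone maps to its true allele."""
        w = build_world(SimulationConfig(
            seed=77, genome_length=1600, n_genes=1, exons_per_gene=(1, 2),
            snp_rate=0.01, conversion_rate=1.0, n_control_sites=0))
        checked = 0
        for mode in ("fertilized", "thelytokous"):
            cs = simulate_clones(w, (50, 1550), mode, 20)
            mat, qc = haplotype_clone_set(cs)
            assert qc["n_unaligned"] == 0
            # recompute assignments to compare against truth labels
            from capemeth.haplotyping import (align_clone_bisulfite,
                                              assign_clone_allele,
                                              classify_snp_informativeness)
            info = classify_snp_informativeness(
                cs.allele_definitions, region_start=cs.start,
                region_length=len(cs.reference))
            for c in cs.clones:
                al = align_clone_bisulfite(c.sequence, cs.reference)
                got = assign_clone_allele(al, info)
                if got != AMBIGUOUS:
                    assert got == cs.truth[c.clone_id][0]
                    checked += 1
        assert checked >= 30

    @pytest.mark.parametrize("regime,expected", [
        ("cis", "cis_asm"), ("poe", "parent_of_origin"),
        ("base", "inconclusive"),
    ])
    def test_regime_recovery(self, regime, expected):
        """Majority of simulated loci get the regime's verdict."""
        hits = 0
        n_loci = 5
        for i in range(n_loci):
            w = self.locus(regime, 4000 + 7 * i)
            mats = {}
            for mode in ("fertilized", "thelytokous"):
                cs = simulate_clones(w, (50, 1550), mode, 20)
                mats[mode], _ = haplotype_clone_set(cs)
            v = classify_poe_vs_asm(mats["fertilized"], mats["thelytokous"])
            hits += v.verdict == expected
        # a clear majority at 5 loci; the full accuracy bound is asserted on
        # 100 loci per regime in the acceptance suite
        assert hits >= 3
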