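import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from skypurge.annotation import (
    GeneModel, annotate_degeneracy, classify_variant_effects, load_gff3,
)
from skypurge.core import MISSING
from skypurge.genetic_load import (
    pi0_pi4_ratio, polarize_to_derived, split_missense_by_score,
    tally_load_ratios,
)


class TestPolarize:
    def test_majority_hom_ref_keeps_dosages(self, gm_factory):
        dos = np.array([[0] * 8 + [1, 2]])
        gm = gm_factory(dos, pops={f"s{i}": "P" for i in range(10)})
        out, table = polarize_to_derived(gm)
        assert table["status"].iloc[0] == "polarized"
        np.testing.assert_array_equal(out.dosage, dos)

    def test_majority_hom_alt_flips(self, gm_factory):
        dos = np.array([[2] * 7 + [0, 1, 0]])
        gm = gm_factory(dos, pops={f"s{i}": "P" for i in range(10)})
        out, table = polarize_to_derived(gm, require_ref_ancestral=False)
        assert table["status"].iloc[0] == "polarized"
        assert table["ancestral"].iloc[0] == "T"
        np.testing.assert_array_equal(out.dosage[0], [0] * 7 + [2, 1, 2])

    def test_nonref_ancestral_excluded_by_default(self, gm_factory):
        dos = np.array([[2] * 7 + [0, 1, 0]])
        gm = gm_factory(dos, pops={f"s{i}": "P" for i in range(10)})
        out, table = polarize_to_derived(gm)
        assert table["status"].iloc[0] == "excluded_nonref"
        assert out.n_sites == 0

    def test_exact_half_is_tie(self, gm_factory):
        dos = np.array([[0] * 5 + [2] * 5])
        gm = gm_factory(dos, pops={f"s{i}": "P" for i in range(10)})
        _, table = polarize_to_derived(gm)
        assert table["status"].iloc[0] == "excluded_tie"

    def test_involution(self, gm_factory):
        rng = np.random.default_rng(0)
        dos = rng.integers(-1, 3, size=(60, 12)).astype(np.int8)
        gm = gm_factory(dos, pops={f"s{i}": "P" for i in range(12)})
        once, _ = polarize_to_derived(gm, require_ref_ancestral=False)
        twice, t2 = polarize_to_derived(once, require_ref_ancestral=False)
        assert (t2["status"] == "polarized").all()
        np.testing.assert_array_equal(once.dosage, twice.dosage)

    def test_majority_validation(self, gm_factory):
        gm = gm_factory(np.zeros((1, 4), dtype=np.int8),
                        pops={f"s{i}": "P" for i in range(4)})
        with pytest.raises(ValueError):
            polarize_to_derived(gm, majority=1.5)


def toy_annotation():
    """One plus-strand and one minus-strand single-exon gene.

    gene1 (+, 1-based 11..28): ATG AAA CAA GGT TGG TAA
    gene2 (-): coding sequence ATG GGG GAT TAA laid on the minus strand.
    """
    g1 = "ATGAAACAAGGTTGGTAA"
    g2_cds = "ATGGGGGATTAA"
    g2 = str(Seq(g2_cds).reverse_complement())
    seq = "T" * 10 + g1 + "ACGTACGTAC" + g2 + "GG" * 5
    g2_start = 10 + len(g1) + 10 + 1
    g2_end = g2_start + len(g2) - 1
    gff = "\n".join([
        "##gff-version 3",
        f"Chr1\ttoy\tgene\t11\t28\t.\t+\t.\tID=gene1",
        f"Chr1\ttoy\tCDS\t11\t28\t.\t+\t0\tParent=gene1",
        f"Chr1\ttoy\tgene\t{g2_start}\t{g2_end}\t.\t-\t.\tID=gene2",
        f"Chr1\ttoy\tCDS\t{g2_start}\t{g2_end}\t.\t-\t0\tParent=gene2",
    ]) + "\n"
    return {"Chr1": seq}, gff, g2_start, g2_end


class TestClassifyEffects:
    def test_plus_strand_classes(self):
        fasta, gff, *_ = toy_annotation()
        sites = pd.DataFrame({
            "chrom": ["Chr1"] * 3,
            # codon 2 (AAA) third base 16; codon 3 (CAA) first base 17;
            # codon 5 (TGG) second base 24
            "pos": [16, 17, 24],
            "ref": ["A", "C", "G"],
            "alt": ["G", "T", "A"],
        })
        ann = classify_variant_effects(sites, gff, fasta)
        assert ann["effect"].tolist() == ["SYN", "LoF", "LoF"]  # AAG syn, TAA stop, TAG stop

    def test_minus_strand_missense(self):
        fasta, gff, g2_start, g2_end = toy_annotation()
        # CDS ATG GGG GAT TAA; codon 2 GGG third base is CDS index 5,
        # genomic pos = g2_end - 5; genomic ref = complement(G) = C
        pos = g2_end - 5
        sites = pd.DataFrame({"chrom": ["Chr1"], "pos": [pos],
                              "ref": ["C"], "alt": ["T"]})
        # CDS alt base = complement(T) = A: GGG -> GGA, still Gly -> SYN
        ann = classify_variant_effects(sites, gff, fasta)
        assert ann["effect"].iloc[0] == "SYN"
        # first base of same codon: CDS index 3, pos = g2_end - 3, ref C
        sites2 = pd.DataFrame({"chrom": ["Chr1"], "pos": [g2_end - 3],
                               "ref": ["C"], "alt": ["T"]})
        # GGG -> AGG: Gly -> Arg missense
        ann2 = classify_variant_effects(sites2, gff, fasta)
        assert ann2["effect"].iloc[0] == "MIS"

    def test_noncoding_site(self):
        fasta, gff, *_ = toy_annotation()
        base = fasta["Chr1"][2]
        alt = "A" if base != "A" else "C"
        sites = pd.DataFrame({"chrom": ["Chr1"], "pos": [3],
                              "ref": [base], "alt": [alt]})
        ann = classify_variant_effects(sites, gff, fasta)
        assert ann["effect"].iloc[0] == "noncoding"

    def test_splice_edge_is_lof(self):
        # two-exon gene with a 10 bp intron
        cds = "ATGAAA" + "CAATAA"
        intron = "GTXXXXXXAG".replace("X", "C")
        seq = "T" * 5 + cds[:6] + intron + cds[6:] + "T" * 5
        gff = "\n".join([
            "Chr1\ttoy\tgene\t6\t27\t.\t+\t.\tID=g",
            "Chr1\ttoy\tCDS\t6\t11\t.\t+\t0\tParent=g",
            "Chr1\ttoy\tCDS\t22\t27\t.\t+\t0\tParent=g",
        ])
        sites = pd.DataFrame({"chrom": ["Chr1"] * 2, "pos": [12, 16],
                              "ref": ["G", "C"], "alt": ["A", "T"]})
        ann = classify_variant_effects(sites, gff, {"Chr1": seq})
        assert ann["effect"].tolist() == ["LoF", "noncoding"]

    def test_cds_not_multiple_of_three_skipped(self):
        seq = "T" * 5 + "ATGAAAA" + "T" * 5
        gff = ("Chr1\ttoy\tgene\t6\t12\t.\t+\t.\tID=g\n"
               "Chr1\ttoy\tCDS\t6\t12\t.\t+\t0\tParent=g\n")
        sites = pd.DataFrame({"chrom": ["Chr1"], "pos": [9],
                              "ref": ["A"], "alt": ["G"]})
        with pytest.warns(UserWarning, match="divisible"):
            ann = classify_variant_effects(sites, gff, {"Chr1": seq})
        assert ann["effect"].iloc[0] == "noncoding"

    def test_randomized_genes_exhaustive_translation_check(self):
        rng = np.random.default_rng(3)
        bases = "ACGT"
        chrom_seq = []
        genes = []
        cursor = 0
        records = []
        for gi in range(20):
            gap = "".join(rng.choice(list(bases), 10))
            chrom_seq.append(gap)
            cursor += 10
            n_codons = int(rng.integers(3, 8))
            cds = "ATG" + "".join(
                rng.choice(list(bases), 3 * (n_codons - 2))) + "TAA"
            strand = "+" if rng.random() < 0.5 else "-"
            genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
            start = cursor + 1
            end = cursor + len(genomic)
            chrom_seq.append(genomic)
            cursor = end
            genes.append(GeneModel(f"g{gi}", "Chr1", strand,
                                   [(start, end, 0)]))
            # one random SNP inside each gene, avoiding start/stop codons
            if n_codons <= 2:
                continue
            cds_idx = int(rng.integers(3, len(cds) - 3))
            codon_i, within = divmod(cds_idx, 3)
            ref_cds = cds[cds_idx]
            alt_cds = rng.choice([b for b in bases if b != ref_cds])
            if strand == "+":
                pos = start + cds_idx
                ref, alt = ref_cds, alt_cds
            else:
                pos = end - cds_idx
                ref = str(Seq(ref_cds).complement())
                alt = str(Seq(alt_cds).complement())
            ref_codon = cds[codon_i * 3:codon_i * 3 + 3]
            alt_codon = ref_codon[:within] + alt_cds + ref_codon[within + 1:]
            aa_ref = str(Seq(ref_codon).translate())
            aa_alt = str(Seq(alt_codon).translate())
            if aa_ref == aa_alt:
                expect = "SYN"
            elif "*" in (aa_ref, aa_alt):
                expect = "LoF"
            else:
                expect = "MIS"
            records.append((pos, ref, alt, expect))
        fasta = {"Chr1": "".join(chrom_seq)}
        sites = pd.DataFrame(records, columns=["pos", "ref", "alt", "expect"])
        sites["chrom"] = "Chr1"
        ann = classify_variant_effects(sites[["chrom", "pos", "ref", "alt"]],
                                       genes, fasta)
        assert ann["effect"].tolist() == sites["expect"].tolist()


class TestDegeneracy:
    def test_known_codon_folds(self):
        seq = "T" * 5 + "ATGGGTTAA" + "T" * 5  # ATG GGT TAA
        gff = ("Chr1\ttoy\tgene\t6\t14\t.\t+\t.\tID=g\n"
               "Chr1\ttoy\tCDS\t6\t14\t.\t+\t0\tParent=g\n")
        deg = annotate_degeneracy(gff, {"Chr1": seq}).set_index("pos")
        # ATG (pos 6-8): all positions 0-fold; GGT (pos 9-11): first position
        # 0-fold, third position 4-fold
        assert deg.loc[6, "fold"] == 0 and deg.loc[8, "fold"] == 0
        assert deg.loc[9, "fold"] == 0
        assert deg.loc[11, "fold"] == 4
        assert set(deg["fold"]).issubset({0, 2, 3, 4})


class TestScoreSplit:
    def _ann(self):
        return pd.DataFrame({
            "chrom": ["Chr1"] * 4, "pos": [10, 20, 30, 40],
            "ref": list("ACGT"), "alt": list("TGCA"),
            "effect": ["MIS", "MIS", "MIS", "SYN"],
        })

    def test_cutoff_boundaries_and_na(self):
        scores = pd.DataFrame({
            "chrom": ["Chr1"] * 3, "pos": [10, 20, 30],
            "alt": ["T", "G", "C"],
            "score": [0.49, 0.50, np.nan],
            "confidence": ["high", "high", "low"],
        })
        out = split_missense_by_score(self._ann(), scores)
        assert out["effect"].tolist() == ["DEL", "TOL", "MIS_excluded", "SYN"]

    def test_score_outside_unit_interval(self):
        scores = pd.DataFrame({"chrom": ["Chr1"], "pos": [10], "alt": ["T"],
                               "score": [1.2], "confidence": ["high"]})
        with pytest.raises(ValueError):
            split_missense_by_score(self._ann(), scores)


class TestLoadRatios:
    def test_hand_tally(self, gm_factory):
        effects = ["SYN"] * 4 + ["DEL"] * 2 + ["LoF", "TOL"]
        # sample0: SYN het at 2 sites, SYN hom at 1; DEL hom at 1; LoF het 1
        dos = np.array([
            [1, 0], [1, 0], [2, 1], [0, 0],
            [2, 0], [0, 1],
            [1, 0], [0, 2],
        ])
        gm = gm_factory(dos, pops={"s0": "P", "s1": "P"})
        ann = pd.DataFrame({"effect": effects})
        per_sample, per_pop = tally_load_ratios(gm, ann)
        row = per_sample.set_index("sample").loc["s0"]
        assert row["SYN_het"] == 2 and row["SYN_hom"] == 1
        assert row["del_syn_hom"] == pytest.approx(1.0)   # 1 hom DEL / 1 hom SYN
        assert row["lof_syn_het"] == pytest.approx(0.5)   # 1 het LoF / 2 het SYN
        assert row["del_syn_het"] == pytest.approx(0.0)

    def test_zero_syn_denominator_undefined(self, gm_factory):
        dos = np.array([[1, 0], [2, 2]])
        gm = gm_factory(dos, pops={"s0": "P", "s1": "P"})
        ann = pd.DataFrame({"effect": ["SYN", "DEL"]})
        per_sample, _ = tally_load_ratios(gm, ann)
        row = per_sample.set_index("sample").loc["s0"]
        assert np.isnan(row["del_syn_hom"])  # no hom SYN for s0

    def test_class_counts_conserve_total_derived_sites(self, gm_factory):
        rng = np.random.default_rng(1)
        effects = rng.choice(["SYN", "TOL", "DEL", "LoF"], size=50)
        dos = rng.integers(-1, 3, size=(50, 6)).astype(np.int8)
        gm = gm_factory(dos, pops={f"s{i}": "P" for i in range(6)})
        per_sample, _ = tally_load_ratios(gm, pd.DataFrame({"effect": effects}))
        for j, s in enumerate(gm.samples):
            carried = int(((dos[:, j] == 1) | (dos[:, j] == 2)).sum())
            row = per_sample.set_index("sample").loc[s]
            total = sum(row[f"{c}_{z}"] for c in ("SYN", "TOL", "DEL", "LoF")
                        for z in ("het", "hom"))
            assert total == carried

    def test_no_syn_sites_errors(self, gm_factory):
        gm = gm_factory(np.array([[1, 1]]), pops={"s0": "P", "s1": "P"})
        with pytest.raises(ValueError, match="SYN"):
            tally_load_ratios(gm, pd.DataFrame({"effect": ["DEL"]}))


class TestPi0Pi4:
    def _deg(self):
        return pd.DataFrame({
            "chrom": ["Chr1"] * 4, "pos": [100, 200, 300, 400],
            "gene": ["g"] * 4, "fold": [0, 0, 4, 4],
        })

    def test_variation_only_at_fourfold_gives_zero(self, gm_factory):
        dos = np.array([[0, 0], [0, 0], [1, 1], [0, 2]])
        gm = gm_factory(dos, pos=[100, 200, 300, 400],
                        pops={"s0": "P", "s1": "P"})
        pi0, pi4, ratio = pi0_pi4_ratio(gm, self._deg(), "P")
        assert pi0 == 0.0 and pi4 > 0 and ratio == 0.0

    def test_equal_diversity_gives_one(self, gm_factory):
        dos = np.array([[0, 2], [0, 2], [0, 2], [0, 2]])
        gm = gm_factory(dos, pos=[100, 200, 300, 400],
                        pops={"s0": "P", "s1": "P"})
        _, _, ratio = pi0_pi4_ratio(gm, self._deg(), "P")
        assert ratio == pytest.approx(1.0)

    def test_monomorphic_sites_count_in_denominator(self, gm_factory):
        # only one of two 0-fold sites is polymorphic: pi0 halves
        dos = np.array([[0, 2], [0, 0], [0, 2], [0, 2]])
        gm = gm_factory(dos, pos=[100, 200, 300, 400],
                        pops={"s0": "P", "s1": "P"})
        pi0, pi4, ratio = pi0_pi4_ratio(gm, self._deg(), "P")
        assert ratio == pytest.approx(0.5)

    def test_zero_pi4_undefined(self, gm_factory):
        dos = np.array([[0, 2], [0, 2], [0, 0], [0, 0]])
        gm = gm_factory(dos, pos=[100, 200, 300, 400],
                        pops={"s0": "P", "s1": "P"})
        *_, ratio = pi0_pi4_ratio(gm, self._deg(), "P")
        assert np.isnan(ratio)
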