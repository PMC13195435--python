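"""Gene-model handling: variant effect classes and codon degeneracy.

Effects are assigned per SNP by locating it in an annotated CDS, rebuilding
the affected codon from the reference sequence (reverse-complemented for
minus-strand genes), and translating ref vs alt codons:

* identical amino acid        -> SYN
* different amino acid        -> MIS
* stop gained / stop lost /
  start lost / splice 2-bp    -> LoF

Degeneracy is the count of the three alternative bases at a CDS position
that preserve the amino acid: fold 4 means all do, fold 0 means none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "GeneModel", "load_gff3", "load_fasta",
    "classify_variant_effects", "annotate_degeneracy",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


@dataclass
class GeneModel:
    """One protein-coding gene: ordered CDS segments on one strand."""

    gene_id: str
    chrom: str
    strand: str                      # '+' or '-'
    cds: list = field(default_factory=list)   # [(start, end, phase)] 1-based inclusive

    @property
    def start(self) -> int:
        return min(s for s, _, _ in self.cds)

    @property
    def end(self) -> int:
        return max(e for _, e, _ in self.cds)

    def splice_edge_positions(self) -> set:
        """Genomic positions of the canonical 2-bp donor/acceptor
        dinucleotides of introns between consecutive CDS segments."""
        out: set = set()
        segs = sorted(self.cds)
        for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
            if s2 > e1 + 1:  # real intron
                out.update((e1 + 1, e1 + 2, s2 - 2, s2 - 1))
        return out


def load_gff3(path_or_text) -> list:
    """Parse gene + CDS features from a GFF3 file (path or literal text)."""
    text = None
    p = str(path_or_text)
    if "\n" in p or "\t" in p:
        text = p
    else:
        with open(p) as fh:
            text = fh.read()
    genes: dict = {}
    strands: dict = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        chrom, _, ftype, start, end, _, strand, phase, attrs = f[:9]
        attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if ftype == "gene":
            gid = attr.get("ID", f"{chrom}:{start}-{end}")
            genes.setdefault(gid, GeneModel(gid, chrom, strand))
            strands[gid] = strand
        elif ftype == "CDS":
            gid = attr.get("Parent", attr.get("ID", f"{chrom}:{start}-{end}"))
            gid = gid.split(".")[0] if gid not in genes and gid.split(".")[0] in genes else gid
            gm = genes.setdefault(gid, GeneModel(gid, chrom, strand))
            ph = 0 if phase in (".", "") else int(phase)
            gm.cds.append((int(start), int(end), ph))
    return [g for g in genes.values() if g.cds]


def load_fasta(path_or_dict) -> dict:
    """Load a reference FASTA into {chrom: sequence}; accepts a dict
    directly for in-memory annotations."""
    if isinstance(path_or_dict, dict):
        return {k: str(v).upper() for k, v in path_or_dict.items()}
    from pyfaidx import Fasta

    fa = Fasta(str(path_or_dict), as_raw=True, rebuild=False)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def _spliced_cds(gene: GeneModel, seq: str) -> tuple[str, list]:
    """Spliced coding sequence in reading orientation plus, per CDS index,
    the genomic position it came from.

    The first segment's phase trims incomplete leading codon bases.
    """
    segs = sorted(gene.cds)
    if gene.strand == "-":
        segs = segs[::-1]
    bases: list = []
    positions: list = []
    for start, end, _ in segs:
        frag = seq[start - 1:end]
        pos = list(range(start, end + 1))
        if gene.strand == "-":
            frag = _revcomp(frag)
            pos = pos[::-1]
        bases.append(frag)
        positions.extend(pos)
    cds_seq = "".join(bases)
    first_phase = segs[0][2]
    if first_phase:
        cds_seq = cds_seq[first_phase:]
        positions = positions[first_phase:]
    return cds_seq, positions


def classify_variant_effects(sites: pd.DataFrame, gff, fasta) -> pd.DataFrame:
    """Classify SNPs into SYN / MIS / LoF / noncoding.

    Parameters
    ----------
    sites : DataFrame with columns chrom, pos, ref, alt (single alt base).
    gff : GFF3 path/text or pre-parsed list of :class:`GeneModel`.
    fasta : FASTA path or {chrom: seq} dict.

    Returns a DataFrame aligned with ``sites`` adding effect, gene,
    codon_change, aa_change columns. Genes whose spliced CDS length is not a
    multiple of 3 are skipped with a warning.
    """
    genes = gff if isinstance(gff, list) else load_gff3(gff)
    seqs = load_fasta(fasta)

    pos_to_effect: dict = {}
    splice_pos: dict = {}
    for gene in genes:
        if gene.chrom not in seqs:
            raise ValueError(f"chromosome {gene.chrom!r} missing from FASTA")
        seq = seqs[gene.chrom]
        if gene.end > len(seq):
            raise ValueError(f"gene {gene.gene_id} extends beyond FASTA bounds")
        for p in gene.splice_edge_positions():
            splice_pos[(gene.chrom, p)] = gene.gene_id
        cds_seq, positions = _spliced_cds(gene, seq)
        if len(cds_seq) % 3 != 0:
            warnings.warn(f"gene {gene.gene_id}: CDS length not divisible by 3; skipped")
            continue
        for idx, gpos in enumerate(positions):
            pos_to_effect[(gene.chrom, gpos)] = (gene, cds_seq, idx)

    rows = []
    for site in sites.itertuples(index=False):
        chrom, pos = str(site.chrom), int(site.pos)
        ref, alt = str(site.ref).upper(), str(site.alt).upper()
        key = (chrom, pos)
        if key in splice_pos:
            rows.append(("LoF", splice_pos[key], "splice", ""))
            continue
        hit = pos_to_effect.get(key)
        if hit is None:
            rows.append(("noncoding", "", "", ""))
            continue
        gene, cds_seq, idx = hit
        codon_i, within = divmod(idx, 3)
        ref_codon = cds_seq[codon_i * 3:codon_i * 3 + 3]
        ref_base = ref if gene.strand == "+" else _revcomp(ref)
        alt_base = alt if gene.strand == "+" else _revcomp(alt)
        if ref_codon[within] != ref_base:
            raise ValueError(
                f"reference mismatch at {chrom}:{pos} in {gene.gene_id}: "
                f"codon has {ref_codon[within]}, VCF ref implies {ref_base}"
            )
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1:]
        aa_ref, aa_alt = _translate(ref_codon), _translate(alt_codon)
        change = f"{ref_codon}>{alt_codon}"
        aa_change = f"{aa_ref}>{aa_alt}"
        if aa_ref == aa_alt:
            effect = "SYN"
        elif aa_alt == "*" or aa_ref == "*":
            effect = "LoF"          # stop gained / stop lost
        elif codon_i == 0 and ref_codon == "ATG":
            effect = "LoF"          # start lost
        else:
            effect = "MIS"
        rows.append((effect, gene.gene_id, change, aa_change))

    out = sites.copy().reset_index(drop=True)
    eff = pd.DataFrame(rows, columns=["effect", "gene", "codon_change", "aa_change"])
    return pd.concat([out, eff], axis=1)


def annotate_degeneracy(gff, fasta) -> pd.DataFrame:
    """Fold degeneracy (0/2/3/4) for every CDS position of every gene.

    Returns a DataFrame (chrom, pos, gene, fold). Positions belonging to
    multiple genes keep the first gene encountered.
    """
    genes = gff if isinstance(gff, list) else load_gff3(gff)
    seqs = load_fasta(fasta)
    seen: set = set()
    rows = []
    bases = "ACGT"
    for gene in genes:
        seq = seqs[gene.chrom]
        cds_seq, positions = _spliced_cds(gene, seq)
        if len(cds_seq) % 3 != 0:
            continue
        for idx, gpos in enumerate(positions):
            key = (gene.chrom, gpos)
            if key in seen:
                continue
            seen.add(key)
            codon_i, within = divmod(idx, 3)
            codon = cds_seq[codon_i * 3:codon_i * 3 + 3]
            aa = _translate(codon)
            syn = sum(
                1 for b in bases
                if b != codon[within]
                and _translate(codon[:within] + b + codon[within + 1:]) == aa
            )
            fold = {0: 0, 1: 2, 2: 3, 3: 4}[syn]
            rows.append((gene.chrom, gpos, gene.gene_id, fold))
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene", "fold"])
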