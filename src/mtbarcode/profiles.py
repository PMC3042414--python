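"""Gene-profile construction from annotated mitochondrial genome records.

A *profile* is one aligned gene region (or concatenation) across all sampled
genomes, with per-sequence taxonomy labels.  From annotated genomes the
package builds 14 profiles: the 12 heavy-strand protein-coding genes (ND6 is
excluded: it lies on the light strand), their concatenation ("genome"), and
the canonical barcoding fragment from the 5' end of CO1 (alignment positions
58-705, 1-based inclusive; 648 columns).

All internal coordinates are 0-based half-open; 1-based inclusive inputs are
converted at the boundary.
"""

from __future__ import annotations

import logging
import re
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from ._seqcodes import GAP_CHARS, IUPAC_NUC, MITO_STOPS

logger = logging.getLogger(__name__)

#: The 12 analysed protein-coding genes, in the alphabetic order used for
#: concatenation.
PCG_GENES = (
    "ATP6", "ATP8", "CO1", "CO2", "CO3", "CytB",
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5",
)

#: Common annotation synonyms -> canonical gene names.
GENE_ALIASES = {
    "COX1": "CO1", "COI": "CO1", "COX2": "CO2", "COII": "CO2",
    "COX3": "CO3", "COIII": "CO3", "COB": "CytB", "CYTB": "CytB",
    "MT-CO1": "CO1", "MT-CO2": "CO2", "MT-CO3": "CO3", "MT-CYB": "CytB",
    "NAD1": "ND1", "NAD2": "ND2", "NAD3": "ND3", "NAD4": "ND4",
    "NAD4L": "ND4L", "NAD5": "ND5", "ATPASE6": "ATP6", "ATPASE8": "ATP8",
    "ATP SYNTHASE 6": "ATP6", "ATP SYNTHASE 8": "ATP8",
}
GENE_ALIASES.update({g.upper(): g for g in PCG_GENES})

SUPERORDERS = (
    "Laurasiatheria", "Euarchontoglires", "Xenarthra", "Afrotheria", "Outgroup",
)

#: Barcoding fragment bounds within the aligned CO1 profile, 0-based half-open
#: (positions 58-705 in the 1-based inclusive convention).
BARCODE_START, BARCODE_END = 57, 705

_VALID_CHARS = set(IUPAC_NUC) | set(GAP_CHARS) | {"U"}


def canonical_gene(name: str) -> str | None:
    """Map an annotation label to a canonical gene name, or None."""
    key = re.sub(r"\s+", " ", name.strip().upper())
    return GENE_ALIASES.get(key)


@dataclass
class GenomeRecord:
    """One annotated mitochondrial genome with taxonomy labels.

    ``gene_coords`` maps gene name -> (start, end, strand) with 0-based
    half-open coordinates and strand in {'+', '-'}.
    """

    accession: str
    species: str
    genus: str
    superorder: str
    sequence: str
    gene_coords: dict[str, tuple[int, int, str]] = field(default_factory=dict)

    def __post_init__(self):
        bad = set(self.sequence.upper()) - _VALID_CHARS
        if bad:
            raise ValueError(f"{self.accession}: invalid characters {sorted(bad)}")


@dataclass
class GeneProfile:
    """One aligned gene region with per-sequence taxonomy.

    ``taxonomy`` maps accession -> (species, genus, superorder);
    ``gene_boundaries`` (concatenated profiles only) maps gene name ->
    (start, end) column interval, 0-based half-open.
    """

    gene: str
    alignment: dict[str, str]
    taxonomy: dict[str, tuple[str, str, str]]
    gene_boundaries: dict[str, tuple[int, int]] | None = None

    def __post_init__(self):
        lengths = {len(s) for s in self.alignment.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene}: unequal aligned lengths {lengths}")
        for acc, seq in self.alignment.items():
            if seq and all(c in GAP_CHARS for c in seq):
                raise ValueError(f"{self.gene}: {acc} is all-gap")

    @property
    def length(self) -> int:
        return len(next(iter(self.alignment.values())))

    @property
    def n_sequences(self) -> int:
        return len(self.alignment)

    def subset(self, accessions) -> "GeneProfile":
        return GeneProfile(
            self.gene,
            {a: self.alignment[a] for a in accessions},
            {a: self.taxonomy[a] for a in accessions},
            self.gene_boundaries,
        )

    def species_of(self, acc: str) -> str:
        return self.taxonomy[acc][0]


@dataclass
class ProfileSet:
    """Named collection of profiles plus the outgroup accession set."""

    profiles: dict[str, GeneProfile]
    outgroup_accessions: set[str] = field(default_factory=set)

    def __getitem__(self, name: str) -> GeneProfile:
        return self.profiles[name]

    def __contains__(self, name: str) -> bool:
        return name in self.profiles

    def names(self) -> list[str]:
        return list(self.profiles)


def extract_gene_sequences(records, gene: str):
    """In-frame unaligned gene sequences from annotated genome records.

    Negative-strand annotations are reverse-complemented.  Records lacking
    the annotation, or carrying malformed coordinates, are skipped and
    reported in the returned log.

    Returns ``(sequences, skipped)`` where ``sequences`` maps accession ->
    nucleotide string and ``skipped`` is a list of (accession, reason).
    """
    if gene not in PCG_GENES:
        raise ValueError(f"unknown gene {gene!r}; expected one of {PCG_GENES}")
    sequences: dict[str, str] = {}
    skipped: list[tuple[str, str]] = []
    for rec in records:
        if gene not in rec.gene_coords:
            skipped.append((rec.accession, "gene not annotated"))
            continue
        start, end, strand = rec.gene_coords[gene]
        if not (0 <= start < end <= len(rec.sequence)):
            skipped.append((rec.accession, f"malformed coordinates ({start}, {end})"))
            continue
        seq = rec.sequence[start:end].upper().replace("U", "T")
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        sequences[rec.accession] = seq
    return sequences, skipped


def filter_profile(seqs: dict[str, str], min_len_frac: float = 0.8,
                   max_ambig_run: int = 30):
    """Drop obviously short sequences and those with long ambiguous runs.

    A sequence is removed when its ungapped length falls below
    ``min_len_frac`` times the median ungapped length, or when it contains a
    run of N's at least ``max_ambig_run`` long.

    Returns ``(kept, removal_log)``.
    """
    if not seqs:
        raise ValueError("empty sequence collection")
    lengths = pd.Series(
        {a: sum(c not in GAP_CHARS for c in s) for a, s in seqs.items()}
    )
    cutoff = min_len_frac * lengths.median()
    n_pattern = re.compile("N{%d,}" % max_ambig_run)
    kept, log = {}, []
    for acc, seq in seqs.items():
        if lengths[acc] < cutoff:
            log.append((acc, "too short"))
        elif n_pattern.search(seq.upper()):
            log.append((acc, "ambiguous run"))
        else:
            kept[acc] = seq
    if not kept:
        raise ValueError("all sequences removed; profile unusable")
    return kept, log


def _codon_is_stop(codon: str) -> bool:
    return codon in MITO_STOPS


def finalize_alignment(gene: str, alignment: dict[str, str],
                       taxonomy: dict[str, tuple], coding: bool = True,
                       max_internal_stop_frac: float = 0.05) -> GeneProfile:
    """Trim terminal stop-codon columns and validate reading frame.

    The final codon column is removed when at least half of the gap-free
    terminal codons are (vertebrate mitochondrial) stops.  An internal stop
    in more than ``max_internal_stop_frac`` of sequences aborts: that
    pattern suggests a frame shift or NUMT-like input.
    """
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment columns must be equal length")
    (length,) = lengths

    aln = {a: s.upper().replace("U", "T") for a, s in alignment.items()}
    if coding and length >= 3:
        last = [s[-3:] for s in aln.values() if "-" not in s[-3:]]
        if last and sum(_codon_is_stop(c) for c in last) >= 0.5 * len(last):
            aln = {a: s[:-3] for a, s in aln.items()}
            length -= 3

    if coding:
        if length % 3 != 0:
            raise ValueError(f"{gene}: length {length} not divisible by 3")
        n_internal = 0
        for seq in aln.values():
            codons = [seq[i : i + 3] for i in range(0, length - 3, 3)]
            if any(_codon_is_stop(c) for c in codons if "-" not in c):
                n_internal += 1
        if n_internal > max_internal_stop_frac * len(aln):
            raise ValueError(
                f"{gene}: internal stop codons in {n_internal}/{len(aln)} "
                "sequences (suspected frame shift or NUMT-like input)"
            )
    return GeneProfile(gene, aln, {a: taxonomy[a] for a in aln})


def build_genome_profile(profile_set: ProfileSet) -> GeneProfile:
    """Concatenate the 12 gene profiles in alphabetic gene-name order.

    Only accessions present in all 12 single-gene profiles are included;
    the rest are logged and excluded.  Gene column intervals are recorded in
    ``gene_boundaries`` for sliding-window annotation.
    """
    missing = [g for g in PCG_GENES if g not in profile_set.profiles]
    if missing:
        raise ValueError(f"profile set lacks genes: {missing}")
    order = sorted(PCG_GENES)
    shared = set.intersection(
        *(set(profile_set[g].alignment) for g in order)
    )
    all_accs = set.union(*(set(profile_set[g].alignment) for g in order))
    for acc in sorted(all_accs - shared):
        logger.info("genome profile: %s missing from some gene profiles", acc)
    if not shared:
        raise ValueError("no accession shared across all 12 gene profiles")

    boundaries: dict[str, tuple[int, int]] = {}
    offset = 0
    for g in order:
        L = profile_set[g].length
        boundaries[g] = (offset, offset + L)
        offset += L
    ordered = sorted(shared)
    alignment = {
        acc: "".join(profile_set[g].alignment[acc] for g in order)
        for acc in ordered
    }
    taxonomy = {acc: profile_set[order[0]].taxonomy[acc] for acc in ordered}
    return GeneProfile("genome", alignment, taxonomy, gene_boundaries=boundaries)


def extract_barcoding_region(co1: GeneProfile) -> GeneProfile:
    """The canonical 648 bp barcoding fragment from the aligned CO1 profile."""
    if co1.length < BARCODE_END:
        raise ValueError(
            f"CO1 profile has {co1.length} columns; need >= {BARCODE_END}"
        )
    alignment = {
        a: s[BARCODE_START:BARCODE_END] for a, s in co1.alignment.items()
    }
    return GeneProfile("barcoding_region", alignment, dict(co1.taxonomy))


def build_profiles(records, min_len_frac: float = 0.8, max_ambig_run: int = 30,
                   aligner_cmd: str | None = None) -> ProfileSet:
    """Full profile construction from annotated genome records.

    Extracts each of the 12 genes, applies QC filtering, optionally runs an
    external aligner (``aligner_cmd`` with ``{in}``/``{out}`` placeholders),
    finalizes alignments, and assembles the genome and barcoding-region
    profiles.  Pre-aligned input (equal-length extractions, as produced by
    the simulator) passes straight through.
    """
    records = cull_duplicates(records)
    taxonomy = {
        r.accession: (r.species, r.genus, r.superorder) for r in records
    }
    outgroup = {r.accession for r in records if r.superorder == "Outgroup"}
    profiles: dict[str, GeneProfile] = {}
    for gene in PCG_GENES:
        seqs, skipped = extract_gene_sequences(records, gene)
        for acc, reason in skipped:
            logger.info("%s: %s skipped (%s)", gene, acc, reason)
        seqs, removed = filter_profile(seqs, min_len_frac, max_ambig_run)
        for acc, reason in removed:
            logger.info("%s: %s removed (%s)", gene, acc, reason)
        if len({len(s) for s in seqs.values()}) > 1:
            if aligner_cmd is None:
                raise ValueError(
                    f"{gene}: unaligned sequences and no aligner command given"
                )
            seqs = run_aligner(seqs, aligner_cmd)
        profiles[gene] = finalize_alignment(gene, seqs, taxonomy)
    pset = ProfileSet(profiles, outgroup)
    profiles["genome"] = build_genome_profile(pset)
    profiles["barcoding_region"] = extract_barcoding_region(profiles["CO1"])
    return pset


def cull_duplicates(records):
    """Drop duplicate accessions, keeping the first occurrence."""
    seen, out = set(), []
    for r in records:
        if r.accession in seen:
            logger.info("duplicate accession %s culled", r.accession)
            continue
        seen.add(r.accession)
        out.append(r)
    return out


def run_aligner(seqs: dict[str, str], command_template: str) -> dict[str, str]:
    """Run an external aligner via a command template.

    The template receives ``{in}`` and ``{out}`` FASTA paths, e.g.
    ``"mafft --quiet {in} > {out}"``.
    """
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        fout = Path(tmp) / "out.fasta"
        write_fasta(seqs, fin)
        cmd = command_template.replace("{in}", str(fin)).replace("{out}", str(fout))
        subprocess.run(cmd, shell=True, check=True)
        if fout.exists():
            return read_fasta(fout)
        raise RuntimeError("aligner produced no output file")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for acc, seq in seqs.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_profile_fasta(profile: GeneProfile, path) -> None:
    write_fasta(profile.alignment, path)


def read_taxonomy_tsv(path) -> dict[str, tuple[str, str, str]]:
    """Taxonomy table: columns accession, species, genus, superorder."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"accession", "species", "genus", "superorder"}
    if not need <= set(df.columns):
        raise ValueError(f"taxonomy table needs columns {sorted(need)}")
    return {
        r.accession: (r.species, r.genus, r.superorder)
        for r in df.itertuples()
    }


def write_taxonomy_tsv(taxonomy: dict[str, tuple], path) -> None:
    pd.DataFrame(
        [(a, *t) for a, t in taxonomy.items()],
        columns=["accession", "species", "genus", "superorder"],
    ).to_csv(path, sep="\t", index=False)


def read_profile_fasta(path, gene: str,
                       taxonomy: dict[str, tuple]) -> GeneProfile:
    """Pre-aligned FASTA for one profile, with taxonomy from a side table."""
    aln = read_fasta(path)
    missing = [a for a in aln if a not in taxonomy]
    if missing:
        raise ValueError(f"taxonomy missing for {missing[:5]}")
    return GeneProfile(gene, aln, {a: taxonomy[a] for a in aln})


def read_coords_tsv(path) -> dict[str, dict[str, tuple[int, int, str]]]:
    """Gene-coordinate table: accession, gene, start, end, strand (0-based
    half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"start": int, "end": int})
    out: dict[str, dict[str, tuple[int, int, str]]] = {}
    for r in df.itertuples():
        gene = canonical_gene(str(r.gene)) or str(r.gene)
        out.setdefault(str(r.accession), {})[gene] = (
            int(r.start), int(r.end), str(r.strand)
        )
    return out


def read_fasta_records(fasta_path, coords_path, taxonomy_path):
    """Genome records from FASTA + coordinate TSV + taxonomy TSV."""
    seqs = read_fasta(fasta_path)
    coords = read_coords_tsv(coords_path)
    taxonomy = read_taxonomy_tsv(taxonomy_path)
    records = []
    for acc, seq in seqs.items():
        if acc not in taxonomy:
            logger.info("no taxonomy for %s; skipped", acc)
            continue
        sp, gen, so = taxonomy[acc]
        records.append(
            GenomeRecord(acc, sp, gen, so, seq, coords.get(acc, {}))
        )
    return cull_duplicates(records)


def read_genbank_records(path, superorders: dict[str, str] | None = None):
    """Genome records from a GenBank flat file.

    Species comes from the ORGANISM annotation; the super-order is looked up
    in ``superorders`` (species -> super-order) or inferred from the taxonomy
    lineage when it names one of the four eutherian super-orders, defaulting
    to ``"Outgroup"``.
    """
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        organism = rec.annotations.get("organism", rec.id)
        genus = organism.split()[0]
        lineage = set(rec.annotations.get("taxonomy", []))
        so = "Outgroup"
        for cand in SUPERORDERS[:4]:
            if cand in lineage:
                so = cand
                break
        if superorders and organism in superorders:
            so = superorders[organism]
        coords = {}
        for feat in rec.features:
            if feat.type not in ("CDS", "gene"):
                continue
            names = feat.qualifiers.get("gene", []) + feat.qualifiers.get(
                "product", []
            )
            for name in names:
                gene = canonical_gene(name)
                if gene and gene not in coords:
                    strand = "-" if feat.location.strand == -1 else "+"
                    coords[gene] = (
                        int(feat.location.start), int(feat.location.end), strand
                    )
        accession = rec.id.split()[0]
        records.append(
            GenomeRecord(accession, organism, genus, so, str(rec.seq).upper(), coords)
        )
    return cull_duplicates(records)


def translate_profile(profile: GeneProfile) -> GeneProfile:
    """Amino-acid translation of a coding profile (vertebrate mito code).

    Codons containing a gap or ambiguity translate to ``-``/``X``; the
    result is an aligned amino-acid profile suitable for aa-Kimura distances
    and ordination.
    """
    if profile.length % 3 != 0:
        raise ValueError("profile length not divisible by 3")
    out = {}
    for acc, seq in profile.alignment.items():
        aas = []
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3].upper()
            if any(c in GAP_CHARS for c in codon):
                aas.append("-")
            elif any(c not in "ACGTU" for c in codon):
                aas.append("X")
            else:
                aas.append(str(Seq(codon).translate(table=2)))
        out[acc] = "".join(aas)
    return GeneProfile(profile.gene + "_aa", out, dict(profile.taxonomy))
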