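"""FASTA alignments: haplotype/genotype collapsing, variation statistics
and seeded per-population subsampling.

Collapsing uses strict full-length symbol identity (case-folded, U->T):
IUPAC ambiguity codes, N, ? and '-' are characters in their own right
and are never matched against compatible homozygous states.  Site
statistics (S, parsimony-informative S_i) count either ACGT states only
(``ambiguity_policy="missing"``, the default) or every symbol as its
own state (``"state"``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError

IUPAC_ALPHABET = set("ACGTRYSWKMBDHVN?-")
AMBIGUITY_CODES = set("RYSWKMBDHV")


@dataclass
class Alignment:
    """Equal-length named sequences over the IUPAC+gap alphabet."""

    names: list[str]
    seqs: dict[str, str]

    def __post_init__(self):
        if len(self.names) != len(set(self.names)):
            dupes = [n for n, c in Counter(self.names).items() if c > 1]
            raise ValidationError(f"duplicate sequence names: {dupes}")
        if set(self.names) != set(self.seqs):
            raise ValidationError("names and sequence keys disagree")
        cleaned = {}
        length = None
        for name in self.names:
            s = self.seqs[name].upper().replace("U", "T")
            bad = set(s) - IUPAC_ALPHABET
            if bad:
                raise ValidationError(
                    f"sequence {name!r} contains non-IUPAC symbols: {sorted(bad)}"
                )
            if length is None:
                length = len(s)
            elif len(s) != length:
                raise ValidationError(
                    f"sequence {name!r} has length {len(s)} != {length}"
                )
            cleaned[name] = s
        self.seqs = cleaned

    @property
    def n_records(self) -> int:
        return len(self.names)

    @property
    def length(self) -> int:
        return len(self.seqs[self.names[0]]) if self.names else 0

    def __iter__(self):
        return ((n, self.seqs[n]) for n in self.names)


def read_fasta(path) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    names = [r.id for r in records]
    return Alignment(names=names, seqs={r.id: str(r.seq) for r in records})


def write_fasta(aln: Alignment, path, wrap: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in aln]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


@dataclass
class CollapseMap:
    """representative name -> member names (identical full sequences)."""

    groups: dict[str, list[str]]

    def __post_init__(self):
        for rep, members in self.groups.items():
            if rep not in members:
                raise ValidationError(
                    f"representative {rep!r} is not a member of its own group"
                )

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def member_of(self) -> dict[str, str]:
        return {m: rep for rep, members in self.groups.items() for m in members}


def collapse_sequences(aln: Alignment) -> tuple[Alignment, CollapseMap]:
    """Group records by exact full-length identity.

    Heterozygote (IUPAC) and unknown symbols are distinct characters,
    so e.g. ``ACRT`` never collapses with ``ACGT`` or ``ACAT``.  The
    representative of a group is its lexicographically smallest member
    name; output records keep the input order of each group's first
    occurrence.
    """
    by_seq: dict[str, list[str]] = {}
    first_pos: dict[str, int] = {}
    for i, (name, seq) in enumerate(aln):
        if seq not in by_seq:
            first_pos[seq] = i
        by_seq.setdefault(seq, []).append(name)
    ordered = sorted(by_seq, key=first_pos.__getitem__)
    groups = {}
    names = []
    seqs = {}
    for seq in ordered:
        members = sorted(by_seq[seq])
        rep = members[0]
        groups[rep] = members
        names.append(rep)
        seqs[rep] = seq
    return Alignment(names=names, seqs=seqs), CollapseMap(groups=groups)


@dataclass(frozen=True)
class AlignmentStats:
    """Table of alignment variation: length, unique sequences, polymorphic
    and parsimony-informative sites."""

    bp: int
    n: int
    K: int
    S: int
    S_i: int

    @property
    def pct_Si(self) -> int:
        return round(100.0 * self.S_i / self.bp)


def alignment_stats(aln: Alignment, ambiguity_policy: str = "missing") -> AlignmentStats:
    """Compute K (unique sequences), S (>=2 counted states at a site) and
    S_i (>=2 states each carried by >=2 sequences)."""
    if aln.n_records == 0:
        raise ValidationError("empty alignment")
    if ambiguity_policy not in ("missing", "state"):
        raise ValidationError(f"unknown ambiguity_policy {ambiguity_policy!r}")
    _, cmap = collapse_sequences(aln)
    S = 0
    S_i = 0
    columns = zip(*(aln.seqs[n] for n in aln.names))
    for col in columns:
        if ambiguity_policy == "missing":
            counts = Counter(c for c in col if c in "ACGT")
        else:
            counts = Counter(col)
        if len(counts) >= 2:
            S += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                S_i += 1
    return AlignmentStats(bp=aln.length, n=aln.n_records, K=cmap.n_groups, S=S, S_i=S_i)


def subsample_one_per_population(
    aln: Alignment, metadata: dict[str, str], seed: int = 1
) -> Alignment:
    """Keep one uniformly chosen record per population (deterministic
    given ``seed``); records stay in input order."""
    missing = [n for n in aln.names if n not in metadata]
    if missing:
        raise ValidationError(f"records missing from metadata: {missing[:5]}")
    rng = np.random.default_rng(seed)
    pops: dict[str, list[str]] = {}
    for name in aln.names:
        pops.setdefault(metadata[name], []).append(name)
    chosen = set()
    for pop in sorted(pops):
        members = sorted(pops[pop])
        chosen.add(members[rng.integers(len(members))])
    names = [n for n in aln.names if n in chosen]
    return Alignment(names=names, seqs={n: aln.seqs[n] for n in names})


METADATA_COLUMNS = ["individual", "population", "nominal_species", "topotype", "species_group"]


def read_metadata(path) -> pd.DataFrame:
    """Read the per-individual metadata TSV (columns: individual,
    population, nominal_species, topotype, species_group)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    for col in ("individual", "population"):
        if col not in df.columns:
            raise ValidationError(f"metadata is missing required column {col!r}")
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df["topotype"] = df["topotype"].replace("", "0").astype(int)
    if df["individual"].duplicated().any():
        raise ValidationError("duplicate individuals in metadata")
    return df[METADATA_COLUMNS]
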