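"""Genome annotation and mutation classification.

Mutations are named by position and bases, e.g. ``"1910aG"`` for an A->G
change at genome position 1910 (1-based).  Annotation maps each position to
the features containing it (genes, promoters, terminators) and classifies a
base change as regulatory, nonsynonymous or silent.  Microviridae genomes
have overlapping reading frames (genes D and E share sequence), so a single
position can belong to several genes; a change is called nonsynonymous if it
alters the protein in any of its frames.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

FEATURE_CLASSES = ("gene", "promoter", "terminator")
REGULATORY_FEATURE_CLASSES = ("promoter", "terminator")

_KEY_RE = re.compile(r"^(\d+)([acgtACGT])([acgtACGT])$")


class MutationKeyError(ValueError):
    """Raised when a mutation key string cannot be parsed."""


def parse_mutation_key(key: str) -> tuple[int, str, str]:
    """Split a key like ``"1910aG"`` into (position, from_base, to_base).

    Bases are case-normalised (ancestral lowercase, derived uppercase is the
    written convention; parsing is case-insensitive).
    """
    m = _KEY_RE.match(key.strip())
    if m is None:
        raise MutationKeyError(f"malformed mutation key: {key!r}")
    pos = int(m.group(1))
    from_base = m.group(2).lower()
    to_base = m.group(3).lower()
    if from_base == to_base:
        raise MutationKeyError(f"mutation key {key!r} has identical bases")
    return pos, from_base, to_base


def format_mutation_key(position: int, from_base: str, to_base: str) -> str:
    return f"{position}{from_base.lower()}{to_base.upper()}"


def reversion_key(key: str) -> str:
    """The key of the back-mutation restoring the ancestral base."""
    pos, f, t = parse_mutation_key(key)
    return format_mutation_key(pos, t, f)


@dataclass(frozen=True)
class Feature:
    feature_id: str
    feature_class: str  # gene | promoter | terminator
    start: int          # 1-based inclusive
    end: int            # 1-based inclusive
    frame_offset: int = 0

    def __post_init__(self):
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval for {self.feature_id}: [{self.start}, {self.end}]")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class GenomeAnnotation:
    """Feature map plus ancestral sequence for a small circular phage genome.

    ``sequence`` is the ancestral genome (plus strand, 1-based positions map
    to ``sequence[pos - 1]``).  ``known_regulatory`` lists positions outside
    annotated regulatory features that are nonetheless known to have
    regulatory effects.  Features may not wrap the origin.
    """

    genome_length: int
    features: list[Feature] = field(default_factory=list)
    sequence: str | None = None
    known_regulatory: frozenset[int] = frozenset()

    def __post_init__(self):
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        for f in self.features:
            if f.end > self.genome_length:
                raise ValueError(
                    f"feature {f.feature_id} extends past genome end "
                    f"({f.end} > {self.genome_length})"
                )
        if self.sequence is not None and len(self.sequence) != self.genome_length:
            raise ValueError("sequence length does not match genome_length")
        self.known_regulatory = frozenset(self.known_regulatory)

    def features_at(self, position: int) -> list[Feature]:
        self._check_position(position)
        return [f for f in self.features if f.contains(position)]

    def ancestral_base(self, position: int) -> str | None:
        if self.sequence is None:
            return None
        self._check_position(position)
        return self.sequence[position - 1].lower()

    def _check_position(self, position: int) -> None:
        if not 1 <= position <= self.genome_length:
            raise ValueError(
                f"position {position} outside genome [1, {self.genome_length}]"
            )

    def codon_index(self, position: int, gene: Feature) -> int | None:
        """1-based codon number of ``position`` within ``gene``, or None if
        the position precedes the gene's reading-frame start."""
        cds_start = gene.start + gene.frame_offset
        if position < cds_start or position > gene.end:
            return None
        return (position - cds_start) // 3 + 1


@dataclass(frozen=True)
class MutationRecord:
    """One genome change, annotated to features and functional class."""

    key: str
    position: int
    from_base: str
    to_base: str
    features: tuple[str, ...] = ()
    functional_class: str = "silent"  # regulatory | nonsynonymous | silent
    cluster_id: str = ""
    intergenic: bool = False

    def __post_init__(self):
        if self.from_base == self.to_base:
            raise ValueError(f"mutation {self.key}: from_base equals to_base")


def _codon_change(annotation: GenomeAnnotation, gene: Feature,
                  position: int, to_base: str) -> tuple[str, str] | None:
    """Ancestral and derived amino acids for the codon hit by ``position``
    in ``gene``'s frame, or None when no sequence is available or the
    position is outside the reading frame."""
    if annotation.sequence is None:
        return None
    idx = annotation.codon_index(position, gene)
    if idx is None:
        return None
    cds_start = gene.start + gene.frame_offset
    codon_start = cds_start + (idx - 1) * 3
    if codon_start + 2 > annotation.genome_length:
        return None
    codon = annotation.sequence[codon_start - 1:codon_start + 2].lower()
    offset = position - codon_start
    derived = codon[:offset] + to_base.lower() + codon[offset + 1:]
    aa_anc = str(Seq(codon).translate())
    aa_der = str(Seq(derived).translate())
    return aa_anc, aa_der


def annotate_mutation(position: int, from_base: str, to_base: str,
                      annotation: GenomeAnnotation) -> MutationRecord:
    """Build an annotated :class:`MutationRecord` for one base change.

    Functional class precedence is regulatory > nonsynonymous > silent:
    a change inside a promoter/terminator (or flagged as known-regulatory)
    is regulatory; otherwise a change that alters the protein in any
    overlapping gene's frame is nonsynonymous; everything else (synonymous
    coding or intergenic) is silent.
    """
    from_base = from_base.lower()
    to_base = to_base.lower()
    feats = annotation.features_at(position)
    anc = annotation.ancestral_base(position)
    effective_to = to_base
    if anc is not None and anc != from_base:
        if anc == to_base:
            # Back-mutation restoring the reference base (the well's own
            # ancestor carried a non-reference base here): classify by the
            # forward change it undoes.
            effective_to = from_base
        else:
            raise ValueError(
                f"position {position}: from_base {from_base!r} does not match "
                f"ancestral base {anc!r}"
            )

    regulatory = (position in annotation.known_regulatory
                  or any(f.feature_class in REGULATORY_FEATURE_CLASSES for f in feats))
    genes = [f for f in feats if f.feature_class == "gene"]
    nonsyn = False
    for g in genes:
        change = _codon_change(annotation, g, position, effective_to)
        if change is not None and change[0] != change[1]:
            nonsyn = True
            break

    if regulatory:
        klass = "regulatory"
    elif nonsyn:
        klass = "nonsynonymous"
    else:
        klass = "silent"

    key = format_mutation_key(position, from_base, to_base)
    record = MutationRecord(
        key=key,
        position=position,
        from_base=from_base,
        to_base=to_base,
        features=tuple(f.feature_id for f in feats),
        functional_class=klass,
        intergenic=not feats,
    )
    return MutationRecord(**{**record.__dict__, "cluster_id": cluster_key(record, annotation)})


def cluster_key(mutation: MutationRecord, annotation: GenomeAnnotation) -> str:
    """Identity of a mutation at the regulatory-element/codon level.

    Mutations in the same promoter or terminator share a cluster; coding
    mutations share a cluster when they alter the same codon of the same
    gene (the first-annotated containing gene is used for genes with
    overlapping reading frames, a deterministic tie-break); everything else
    is its own singleton cluster.
    """
    feats = annotation.features_at(mutation.position)
    reg = [f for f in feats if f.feature_class in REGULATORY_FEATURE_CLASSES]
    if reg:
        return "|".join(sorted(f.feature_id for f in reg))
    for g in feats:
        if g.feature_class != "gene":
            continue
        idx = annotation.codon_index(mutation.position, g)
        if idx is not None:
            return f"{g.feature_id}:{idx}"
    return mutation.key


# ---------------------------------------------------------------------------
# Annotation I/O: BED-like feature TSV plus a FASTA ancestral genome
# ---------------------------------------------------------------------------

def read_annotation(features_path, fasta_path=None,
                    genome_length: int | None = None) -> GenomeAnnotation:
    """Load an annotation from a feature table and optional genome FASTA.

    The feature table is a TSV with columns
    ``feature_id, class, start, end, frame_offset`` (1-based inclusive
    coordinates).  When a FASTA is given its first record is the ancestral
    genome and fixes the genome length; otherwise ``genome_length`` must be
    supplied.
    """
    import pandas as pd

    df = pd.read_csv(features_path, sep="\t", comment="#")
    if "frame_offset" not in df.columns:
        df["frame_offset"] = 0
    features = [
        Feature(str(row["feature_id"]), str(row["class"]),
                int(row["start"]), int(row["end"]), int(row["frame_offset"]))
        for _, row in df.iterrows()
    ]
    sequence = None
    if fasta_path is not None:
        from Bio import SeqIO

        record = next(SeqIO.parse(fasta_path, "fasta"))
        sequence = str(record.seq).lower()
        genome_length = len(sequence)
    if genome_length is None:
        raise ValueError("need either a FASTA genome or genome_length")
    return GenomeAnnotation(genome_length=genome_length, features=features,
                            sequence=sequence)


def write_annotation(annotation: GenomeAnnotation, features_path,
                     fasta_path=None) -> None:
    import pandas as pd

    pd.DataFrame(
        [(f.feature_id, f.feature_class, f.start, f.end, f.frame_offset)
         for f in annotation.features],
        columns=["feature_id", "class", "start", "end", "frame_offset"],
    ).to_csv(features_path, sep="\t", index=False)
    if fasta_path is not None and annotation.sequence is not None:
        with open(fasta_path, "w") as fh:
            fh.write(">ancestral\n")
            seq = annotation.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
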