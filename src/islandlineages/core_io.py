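"""Domain types, variant-token grammar, variant calling and file I/O.

Coordinates are 1-based inclusive throughout, following the rCRS convention
for human mtDNA.  A variant is expressed relative to the packaged reference
sequence in the token notation used by mtDNA phylogenetics: a bare position
(``"4025"``) is a transition, a position with an explicit base whose class
differs from the reference (``"16360A"``) is a transversion, a trailing
``d`` (``"523d"``) is a deletion and a dotted sub-position (``"310.1C"``)
is an insertion after that position.

The packaged reference (``data/reference_synthetic.fa``) is a synthetic
16,569-bp stand-in laid out on rCRS coordinates: base composition is random
but the positions whose reference state the analyses depend on (the 303-315
poly-C tract, 16182/16183, 16360, 16519) are pinned to their documented
states.  The packaged protein-coding gene map uses the standard 13-gene
human mtDNA annotation (including the ND6 light-strand gene and the
ATP8/ATP6 and ND4L/ND4 overlaps).
"""

from __future__ import annotations

import csv
import enum
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "MT_LENGTH",
    "HVS1_SEQUENCED",
    "HVS1_RHO",
    "CODING_RHO",
    "CODING_FRAGMENTS",
    "YFILER_SINGLE_COPY_LOCI",
    "YFILER_LOCI",
    "RegionSpec",
    "MutationKind",
    "MutationClass",
    "Variant",
    "StrProfile",
    "GenealogyRecord",
    "MtSample",
    "GeneSpan",
    "IslandLineagesError",
    "TokenError",
    "CoordinateError",
    "AlignmentError",
    "SchemaError",
    "IntegrityError",
    "load_reference",
    "load_gene_map",
    "parse_variant_token",
    "format_variant",
    "normalize_token",
    "is_hotspot",
    "call_variants",
    "classify_mutation",
    "synonymous_transition_sites",
    "read_fasta",
    "write_fasta",
    "read_str_profiles",
    "write_str_profiles",
    "read_genealogy",
    "write_genealogy",
    "read_mt_samples",
    "write_mt_samples",
]


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class IslandLineagesError(Exception):
    """Base class for all package-specific errors."""


class TokenError(IslandLineagesError, ValueError):
    """A variant token does not match the grammar."""


class CoordinateError(IslandLineagesError, ValueError):
    """A position falls outside the reference molecule."""


class AlignmentError(IslandLineagesError, ValueError):
    """Sequence and reference lengths/coordinates are inconsistent."""


class SchemaError(IslandLineagesError, ValueError):
    """A tabular input is missing required columns."""


class IntegrityError(IslandLineagesError, ValueError):
    """A tabular input violates uniqueness constraints."""


# --------------------------------------------------------------------------
# Regions and constants
# --------------------------------------------------------------------------

MT_LENGTH = 16569

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class RegionSpec:
    """A named 1-based inclusive interval on the mtDNA reference."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CoordinateError(f"region {self.name}: start {self.start} > end {self.end}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


#: Sequenced portion of hypervariable segment 1.
HVS1_SEQUENCED = RegionSpec("HVS1_SEQUENCED", 16037, 16365)
#: HVS-1 window used for transition counting in molecular dating.
HVS1_RHO = RegionSpec("HVS1_RHO", 16090, 16365)
#: Coding-region window used for synonymous-mutation dating.
CODING_RHO = RegionSpec("CODING_RHO", 590, 15990)
#: Coding fragments covered by partial sequencing.
CODING_FRAGMENTS = (
    RegionSpec("CODING_8000_9000", 8000, 9000),
    RegionSpec("CODING_9800_10900", 9800, 10900),
    RegionSpec("CODING_14000_15000", 14000, 15000),
)


class MutationKind(str, enum.Enum):
    TRANSITION = "transition"
    TRANSVERSION = "transversion"
    INSERTION = "insertion"
    DELETION = "deletion"


class MutationClass(str, enum.Enum):
    """Functional class of a variant, as used by the dating calibrations.

    ``SYNONYMOUS_CODING`` covers silent substitutions (transitions and
    transversions alike) in protein-coding genes; a site in overlapping
    genes is synonymous only if silent in every reading frame.
    """

    SYNONYMOUS_CODING = "synonymous_coding"
    NONSYNONYMOUS = "nonsynonymous"
    HVS1_TRANSITION = "hvs1_transition"
    OTHER = "other"


# --------------------------------------------------------------------------
# Variant
# --------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Variant:
    """One mtDNA polymorphism relative to the reference.

    ``position`` is the 1-based anchor coordinate; insertions additionally
    carry ``insert_index`` >= 1 (the ``.1`` in ``310.1C``).  ``derived`` is
    the derived base for substitutions, the inserted sequence for
    insertions, and ``"-"`` for deletions.
    """

    position: int
    derived: str
    kind: MutationKind
    insert_index: int = 0

    def __post_init__(self) -> None:
        if self.position < 1 or self.position > MT_LENGTH:
            raise CoordinateError(f"position {self.position} outside 1..{MT_LENGTH}")
        if self.kind is MutationKind.INSERTION and self.insert_index < 1:
            raise TokenError("insertions require a dotted sub-index >= 1")
        if self.kind is not MutationKind.INSERTION and self.insert_index != 0:
            raise TokenError("only insertions carry a sub-index")

    def __str__(self) -> str:
        return format_variant(self)


def format_variant(v: Variant) -> str:
    """Canonical token for a variant (transitions print as the bare position)."""
    if v.kind is MutationKind.TRANSITION:
        return str(v.position)
    if v.kind is MutationKind.TRANSVERSION:
        return f"{v.position}{v.derived}"
    if v.kind is MutationKind.DELETION:
        return f"{v.position}d"
    return f"{v.position}.{v.insert_index}{v.derived}"


_TOKEN_RE = re.compile(
    r"""^(?:
        (?P<pos>\d+)(?P<base>[ACGT])?          # substitution (bare = transition)
        | (?P<dpos>\d+)d                       # deletion
        | (?P<ipos>\d+)\.(?P<idx>\d+)(?P<ins>[ACGT]+)   # insertion
    )$""",
    re.VERBOSE,
)


def parse_variant_token(token: str, reference: str | None = None) -> Variant:
    """Parse one Phylotree-style variant token.

    A bare position is a transition away from the reference base; an
    explicit trailing base is typed by comparing purine/pyrimidine class
    with the reference.  ``reference`` defaults to the packaged reference.
    """
    if not token or not token.strip():
        raise TokenError("empty variant token")
    token = token.strip()
    m = _TOKEN_RE.match(token)
    if m is None:
        raise TokenError(f"malformed variant token: {token!r}")
    if reference is None:
        reference = load_reference()

    if m.group("ipos") is not None:
        pos = int(m.group("ipos"))
        _check_range(pos, reference, token)
        return Variant(pos, m.group("ins"), MutationKind.INSERTION, int(m.group("idx")))
    if m.group("dpos") is not None:
        pos = int(m.group("dpos"))
        _check_range(pos, reference, token)
        return Variant(pos, "-", MutationKind.DELETION)

    pos = int(m.group("pos"))
    _check_range(pos, reference, token)
    ref_base = reference[pos - 1].upper()
    base = m.group("base")
    if base is None:
        return Variant(pos, _TRANSITION_PARTNER[ref_base], MutationKind.TRANSITION)
    if base == ref_base:
        raise TokenError(f"token {token!r}: derived base equals the reference state")
    same_class = (base in PURINES) == (ref_base in PURINES)
    kind = MutationKind.TRANSITION if same_class else MutationKind.TRANSVERSION
    return Variant(pos, base, kind)


def _check_range(pos: int, reference: str, token: str) -> None:
    if pos < 1 or pos > len(reference):
        raise CoordinateError(
            f"token {token!r}: position {pos} outside 1..{len(reference)}"
        )


def normalize_token(token: str, reference: str | None = None) -> str:
    """Canonical form of a token: ``format(parse(token))``."""
    return format_variant(parse_variant_token(token, reference))


# --------------------------------------------------------------------------
# Hotspot exclusion
# --------------------------------------------------------------------------

#: Default mutational-hotspot filter: the 16519 transition, indels in the
#: 303-315 poly-C tract (covering the 309/310/315 length variants), and the
#: 16182C/16183C poly-C companion transversions.  These recur so often that
#: networks and haplotype comparisons conventionally leave them out.
DEFAULT_HOTSPOTS = {
    "transition_positions": frozenset({16519}),
    "indel_region": (303, 315),
    "excluded_tokens": frozenset({(16182, "C"), (16183, "C")}),
}


def is_hotspot(v: Variant, hotspots: Mapping | None = None) -> bool:
    hs = DEFAULT_HOTSPOTS if hotspots is None else hotspots
    if v.kind is MutationKind.TRANSITION and v.position in hs["transition_positions"]:
        return True
    lo, hi = hs["indel_region"]
    if v.kind in (MutationKind.INSERTION, MutationKind.DELETION) and lo <= v.position <= hi:
        return True
    return (v.position, v.derived) in hs["excluded_tokens"]


def drop_hotspots(variants: Iterable[Variant], hotspots: Mapping | None = None) -> frozenset[Variant]:
    return frozenset(v for v in variants if not is_hotspot(v, hotspots))


# --------------------------------------------------------------------------
# Samples, profiles, genealogy
# --------------------------------------------------------------------------

#: The 15 single-copy Yfiler loci plus the DYS385 duplicated locus make up
#: the 16-locus panel.  DYS389II is stored as reported (no DYS389I
#: subtraction) so that step distances are reproducible.
YFILER_SINGLE_COPY_LOCI = (
    "DYS19", "DYS389I", "DYS389II", "DYS390", "DYS391", "DYS392", "DYS393",
    "DYS437", "DYS438", "DYS439", "DYS448", "DYS456", "DYS458", "DYS635",
    "YGATAH4",
)
YFILER_LOCI = YFILER_SINGLE_COPY_LOCI + ("DYS385",)


@dataclass(frozen=True)
class StrProfile:
    """A 16-locus Y-STR haplotype with its Y-SNP haplogroup label.

    ``repeats`` maps each single-copy locus to its repeat count; the
    duplicated DYS385 locus is stored as an unordered (sorted) pair.
    """

    sample_id: str
    haplogroup: str
    repeats: Mapping[str, int]
    dys385: tuple[int, int]
    population: str = ""

    def __post_init__(self) -> None:
        missing = set(YFILER_SINGLE_COPY_LOCI) - set(self.repeats)
        if missing:
            raise SchemaError(f"{self.sample_id}: missing loci {sorted(missing)}")
        extra = set(self.repeats) - set(YFILER_SINGLE_COPY_LOCI)
        if extra:
            raise SchemaError(f"{self.sample_id}: unknown loci {sorted(extra)}")
        if any(int(r) <= 0 for r in self.repeats.values()) or any(r <= 0 for r in self.dys385):
            raise SchemaError(f"{self.sample_id}: repeat counts must be positive")
        object.__setattr__(self, "repeats", dict(self.repeats))
        object.__setattr__(self, "dys385", tuple(sorted(self.dys385)))

    def vector(self, loci: Sequence[str] = YFILER_SINGLE_COPY_LOCI) -> tuple[int, ...]:
        """Repeat counts over the single-copy loci, in canonical order."""
        return tuple(int(self.repeats[l]) for l in loci)

    def __eq__(self, other) -> bool:  # dict field defeats the generated eq
        if not isinstance(other, StrProfile):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.haplogroup == other.haplogroup
            and self.population == other.population
            and dict(self.repeats) == dict(other.repeats)
            and self.dys385 == other.dys385
        )

    def __hash__(self) -> int:
        return hash((self.sample_id, self.haplogroup, self.vector(), self.dys385))


@dataclass(frozen=True)
class GenealogyRecord:
    """One man's village, ancestral family and extended family."""

    sample_id: str
    village: str
    ancestral_family: str
    extended_family: int


@dataclass(frozen=True)
class MtSample:
    """An mtDNA haplotype as a hotspot-filtered variant set."""

    sample_id: str
    population: str
    variants: frozenset[Variant]
    sequence: str | None = None

    @classmethod
    def from_variants(
        cls,
        sample_id: str,
        population: str,
        variants: Iterable[Variant],
        sequence: str | None = None,
        hotspots: Mapping | None = None,
    ) -> "MtSample":
        return cls(sample_id, population, drop_hotspots(variants, hotspots), sequence)

    def tokens(self) -> list[str]:
        return sorted(
            (format_variant(v) for v in self.variants),
            key=lambda t: (int(re.match(r"\d+", t).group()), t),
        )


# --------------------------------------------------------------------------
# Packaged reference and gene map
# --------------------------------------------------------------------------

_REFERENCE: str | None = None
_GENE_MAP: tuple | None = None


@dataclass(frozen=True)
class GeneSpan:
    """A protein-coding gene span with strand ('+' heavy, '-' light)."""

    name: str
    start: int
    end: int
    strand: str

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


def _data_path(name: str) -> Path:
    return Path(resources.files("islandlineages").joinpath("data", name))


def load_reference() -> str:
    """The packaged synthetic mtDNA reference sequence (16,569 bp)."""
    global _REFERENCE
    if _REFERENCE is None:
        record = next(SeqIO.parse(_data_path("reference_synthetic.fa"), "fasta"))
        _REFERENCE = str(record.seq).upper()
        if len(_REFERENCE) != MT_LENGTH:
            raise IntegrityError("packaged reference has unexpected length")
    return _REFERENCE


def load_gene_map() -> tuple[GeneSpan, ...]:
    """The packaged 13-gene protein-coding annotation."""
    global _GENE_MAP
    if _GENE_MAP is None:
        spans = []
        with open(_data_path("mt_gene_map.tsv")) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                spans.append(
                    GeneSpan(row["gene"], int(row["start"]), int(row["end"]), row["strand"])
                )
        _GENE_MAP = tuple(spans)
    return _GENE_MAP


# --------------------------------------------------------------------------
# Variant calling
# --------------------------------------------------------------------------

def call_variants(
    sequence: str,
    reference: str | None = None,
    region: RegionSpec | None = None,
    hotspots: Mapping | None = None,
) -> frozenset[Variant]:
    """Differences between an aligned sequence and the reference in a region.

    ``sequence`` must either span the whole reference or exactly the region
    (both may contain ``-`` gaps for indels, encoded identically in both
    strings' coordinate system).  Hotspot-excluded variants are removed.
    """
    if reference is None:
        reference = load_reference()
    reference = reference.upper()
    sequence = sequence.upper()
    if region is None:
        region = RegionSpec("full", 1, len(reference.replace("-", "")))

    ref_ungapped_len = len(reference.replace("-", ""))
    if len(sequence) != len(reference):
        # Allow a region-sized window against the full reference.
        if len(sequence) == region.length and ref_ungapped_len >= region.end:
            reference = reference[region.start - 1 : region.end]
            offset = region.start - 1
        else:
            raise AlignmentError(
                f"sequence length {len(sequence)} matches neither the reference "
                f"({len(reference)}) nor region {region.name} ({region.length})"
            )
    else:
        offset = 0

    variants: set[Variant] = set()
    pos = offset  # last consumed reference coordinate (1-based)
    insert_idx = 0
    for ref_base, seq_base in zip(reference, sequence):
        if ref_base == "-":
            if seq_base != "-":
                insert_idx += 1
                variants.add(Variant(pos, seq_base, MutationKind.INSERTION, insert_idx))
            continue
        pos += 1
        insert_idx = 0
        if pos < region.start or pos > region.end:
            continue
        if seq_base == "-":
            variants.add(Variant(pos, "-", MutationKind.DELETION))
        elif seq_base != ref_base:
            if seq_base not in "ACGT":
                continue  # ambiguity codes are not called
            same_class = (seq_base in PURINES) == (ref_base in PURINES)
            kind = MutationKind.TRANSITION if same_class else MutationKind.TRANSVERSION
            variants.add(Variant(pos, seq_base, kind))
    return drop_hotspots(variants, hotspots)


# --------------------------------------------------------------------------
# Mutation classification
# --------------------------------------------------------------------------

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _translate_codon(codon: str) -> str:
    if codon in _MITO_TABLE.stop_codons:
        return "*"
    return _MITO_TABLE.forward_table.get(codon, "X")


def _codon_change(v: Variant, gene: GeneSpan, reference: str) -> tuple[str, str] | None:
    """(ref_aa, alt_aa) for a substitution inside ``gene``; None if the
    affected codon is incomplete (runs past the annotated gene end)."""
    if gene.strand == "+":
        off = v.position - gene.start
        codon_start = gene.start + 3 * (off // 3)
        if codon_start + 2 > gene.end:
            return None
        codon = reference[codon_start - 1 : codon_start + 2]
        mutated = list(codon)
        mutated[off % 3] = v.derived
    else:
        off = gene.end - v.position
        codon_end = gene.end - 3 * (off // 3)
        if codon_end - 2 < gene.start:
            return None
        codon = "".join(_COMPLEMENT[b] for b in reversed(reference[codon_end - 3 : codon_end]))
        mutated = list(codon)
        mutated[off % 3] = _COMPLEMENT[v.derived]
    return _translate_codon(codon), _translate_codon("".join(mutated))


def classify_mutation(
    v: Variant,
    gene_map: Sequence[GeneSpan] | None = None,
    reference: str | None = None,
) -> MutationClass:
    """Functional class of a variant.

    Substitutions in protein-coding genes are translated under the
    vertebrate mitochondrial code; control-region variants are never
    synonymous; indels are always ``OTHER``.
    """
    if reference is None:
        reference = load_reference()
    if v.position > len(reference):
        raise CoordinateError(f"variant position {v.position} outside the reference")
    if gene_map is None:
        gene_map = load_gene_map()

    if v.kind in (MutationKind.INSERTION, MutationKind.DELETION):
        return MutationClass.OTHER
    if v.position in HVS1_RHO and v.kind is MutationKind.TRANSITION:
        return MutationClass.HVS1_TRANSITION

    covering = [g for g in gene_map if v.position in g]
    if not covering:
        return MutationClass.OTHER
    changes = [_codon_change(v, g, reference) for g in covering]
    if any(c is None for c in changes):
        return MutationClass.OTHER
    if all(ref_aa == alt_aa for ref_aa, alt_aa in changes):
        return MutationClass.SYNONYMOUS_CODING
    return MutationClass.NONSYNONYMOUS


_SYN_SITES: tuple[int, ...] | None = None


def synonymous_transition_sites(
    region: RegionSpec = CODING_RHO,
    gene_map: Sequence[GeneSpan] | None = None,
    reference: str | None = None,
) -> tuple[int, ...]:
    """Positions in ``region`` where the transition is a synonymous coding
    change on the packaged reference (cached for the default arguments)."""
    global _SYN_SITES
    default = gene_map is None and reference is None and region is CODING_RHO
    if default and _SYN_SITES is not None:
        return _SYN_SITES
    if reference is None:
        reference = load_reference()
    if gene_map is None:
        gene_map = load_gene_map()
    sites = []
    for pos in range(region.start, region.end + 1):
        ref_base = reference[pos - 1]
        v = Variant(pos, _TRANSITION_PARTNER[ref_base], MutationKind.TRANSITION)
        if classify_mutation(v, gene_map, reference) is MutationClass.SYNONYMOUS_CODING:
            sites.append(pos)
    result = tuple(sites)
    if default:
        _SYN_SITES = result
    return result


# --------------------------------------------------------------------------
# File I/O
# --------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n{sequences[name]}\n")


def _read_table(path, required: Sequence[str]) -> list[dict]:
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file")
        missing = set(required) - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
        rows = list(reader)
    if not rows:
        warnings.warn(f"{path}: header-only file, no records", stacklevel=3)
    return rows


def _check_unique(ids: Sequence[str], path) -> None:
    seen = set()
    for sid in ids:
        if sid in seen:
            raise IntegrityError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)


STR_COLUMNS = ("sample_id", "population", "haplogroup") + YFILER_SINGLE_COPY_LOCI + (
    "DYS385a", "DYS385b",
)


def read_str_profiles(path) -> list[StrProfile]:
    rows = _read_table(path, STR_COLUMNS)
    _check_unique([r["sample_id"] for r in rows], path)
    profiles = []
    for i, row in enumerate(rows, start=2):
        try:
            repeats = {l: int(row[l]) for l in YFILER_SINGLE_COPY_LOCI}
            dys385 = (int(row["DYS385a"]), int(row["DYS385b"]))
        except ValueError as exc:
            raise SchemaError(f"{path}:{i}: non-integer repeat count ({exc})") from exc
        profiles.append(
            StrProfile(row["sample_id"], row["haplogroup"], repeats, dys385, row["population"])
        )
    return profiles


def write_str_profiles(profiles: Iterable[StrProfile], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(STR_COLUMNS)
        for p in profiles:
            writer.writerow(
                [p.sample_id, p.population, p.haplogroup]
                + [p.repeats[l] for l in YFILER_SINGLE_COPY_LOCI]
                + list(p.dys385)
            )


GENEALOGY_COLUMNS = ("sample_id", "village", "ancestral_family", "extended_family")


def read_genealogy(path, known_villages: Iterable[str] | None = None) -> list[GenealogyRecord]:
    rows = _read_table(path, GENEALOGY_COLUMNS)
    _check_unique([r["sample_id"] for r in rows], path)
    known = set(known_villages) if known_villages is not None else None
    records = []
    ext_to_anc: dict[int, str] = {}
    for i, row in enumerate(rows, start=2):
        rec = GenealogyRecord(
            row["sample_id"], row["village"], row["ancestral_family"], int(row["extended_family"])
        )
        if known is not None and rec.village not in known:
            warnings.warn(f"{path}:{i}: unknown village {rec.village!r}", stacklevel=3)
        prior = ext_to_anc.setdefault(rec.extended_family, rec.ancestral_family)
        if prior != rec.ancestral_family:
            # A valid patrilineal survey maps each extended family to one
            # ancestral family; report violations rather than reject them.
            warnings.warn(
                f"{path}:{i}: extended family {rec.extended_family} spans ancestral "
                f"families {prior!r} and {rec.ancestral_family!r}",
                stacklevel=3,
            )
        records.append(rec)
    return records


def write_genealogy(records: Iterable[GenealogyRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(GENEALOGY_COLUMNS)
        for r in records:
            writer.writerow([r.sample_id, r.village, r.ancestral_family, r.extended_family])


MT_COLUMNS = ("sample_id", "population", "variants")


def read_mt_samples(path, reference: str | None = None) -> list[MtSample]:
    rows = _read_table(path, MT_COLUMNS)
    _check_unique([r["sample_id"] for r in rows], path)
    if reference is None:
        reference = load_reference()
    samples = []
    for row in rows:
        tokens = row["variants"].split()
        variants = [parse_variant_token(t, reference) for t in tokens]
        samples.append(MtSample.from_variants(row["sample_id"], row["population"], variants))
    return samples


def write_mt_samples(samples: Iterable[MtSample], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(MT_COLUMNS)
        for s in samples:
            writer.writerow([s.sample_id, s.population, " ".join(s.tokens())])
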