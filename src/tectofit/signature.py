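"""Loop-receptor sequence signatures: variants, pairing, distances, consensus.

The THF riboswitch loop docks onto the 3' strand of its receptor through a
long-range Watson-Crick pairing between loop positions 8-12 and receptor
positions 22-18 (the fixed pair map 8:22, 9:21, 10:20, 11:19, 12:18).
Constructs are named by a short identifier, an optional stem-connector
length ("_9", "_10"; 11 bp is the default) and an optional artificial-variant
suffix (".1", ".2", ...), e.g. "980_9" or "4LVV_9.1".

This module represents variants on the positional label scheme of
:mod:`tectofit.positions`, classifies base pairs (Watson-Crick / wobble /
mismatch), computes point-mutation distances, groups variants into sequence
families, and derives IUPAC consensus strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .positions import is_valid_label, label_key, sort_labels

__all__ = [
    "PairClass",
    "LoopReceptorVariant",
    "SignatureAlignment",
    "PairingProfile",
    "parse_variant_name",
    "classify_pair",
    "pairing_profile",
    "point_mutation_distance",
    "family_components",
    "consensus",
    "read_fasta",
    "write_fasta",
    "signature_report",
    "PAIR_MAP",
]

RNA_BASES = frozenset("ACGU")

#: Fixed long-range pair map: loop position -> 3' receptor-strand position.
PAIR_MAP: tuple[tuple[str, str], ...] = (
    ("8", "22"),
    ("9", "21"),
    ("10", "20"),
    ("11", "19"),
    ("12", "18"),
)

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


class PairClass(Enum):
    """Classification of one long-range base combination."""

    WATSON_CRICK = "WC"
    WOBBLE = "wobble"
    MISMATCH = "mismatch"
    UNPAIRED = "unpaired"


@dataclass(frozen=True)
class LoopReceptorVariant:
    """One loop-receptor signature on the positional label scheme.

    ``residues`` maps position label -> base; a canonical position missing
    from the mapping is a deletion, a fractional label ("6.1") an insertion.
    The stem connector is metadata (``stem_length_bp``), not sequence.
    """

    id: str
    residues: Mapping[str, str]
    base_id: str = ""
    stem_length_bp: int = 11
    variant_suffix: Optional[str] = None
    source: str = "natural"

    def __post_init__(self):
        if self.stem_length_bp not in (9, 10, 11):
            raise ValueError(
                f"{self.id}: stem_length_bp must be 9, 10 or 11, "
                f"got {self.stem_length_bp}"
            )
        for label, base in self.residues.items():
            if not is_valid_label(label):
                raise ValueError(f"{self.id}: malformed position label {label!r}")
            if base not in RNA_BASES:
                raise ValueError(
                    f"{self.id}: residue at {label} must be one of A,C,G,U, "
                    f"got {base!r}"
                )
        if not self.base_id:
            object.__setattr__(self, "base_id", self.id)

    @property
    def labels(self) -> list[str]:
        return sort_labels(self.residues)

    def sequence(self) -> str:
        """Residues concatenated 5'->3' in label order (deletions skipped)."""
        return "".join(self.residues[l] for l in self.labels)


@dataclass
class SignatureAlignment:
    """A set of variants laid out over the union of their position labels."""

    variants: list[LoopReceptorVariant]

    @property
    def columns(self) -> list[str]:
        labels: set[str] = set()
        for v in self.variants:
            labels.update(v.residues)
        return sort_labels(labels)

    def column(self, label: str) -> list[Optional[str]]:
        """Residue (or None for gap) of every variant at *label*."""
        return [v.residues.get(label) for v in self.variants]


@dataclass
class PairingProfile:
    """The five classified long-range pairs of one variant."""

    pairs: list[tuple[tuple[str, str], PairClass]]
    gc_count: int


_NAME_RE = re.compile(
    r"^(?P<base>.+?)(?:_(?P<stem>[0-9]+))?(?:\.(?P<suffix>[0-9]+))?$"
)


def parse_variant_name(name: str) -> tuple[str, int, Optional[str]]:
    """Split a construct name into (base_id, stem_length_bp, variant_suffix).

    "_9"/"_10"/"_11" tokens set the stem-connector length (default 11 bp);
    a trailing ".k" token marks an artificial variant.

    >>> parse_variant_name("980_9")
    ('980', 9, None)
    >>> parse_variant_name("4LVV_9.1")
    ('4LVV', 9, '1')
    """
    if not name:
        raise ValueError("empty construct name")
    m = _NAME_RE.match(name)
    if m is None:  # pragma: no cover - regex accepts any non-empty string
        raise ValueError(f"malformed construct name: {name!r}")
    base, stem, suffix = m.group("base"), m.group("stem"), m.group("suffix")
    if stem is None:
        stem_length = 11
    else:
        stem_length = int(stem)
        if stem_length not in (9, 10, 11):
            raise ValueError(
                f"malformed stem-length token '_{stem}' in {name!r}: "
                "connector must be 9, 10 or 11 bp"
            )
    return base, stem_length, suffix


def classify_pair(base_loop: Optional[str], base_receptor: Optional[str]) -> PairClass:
    """Classify a loop/receptor base combination.

    ``None`` for either partner (a deleted position) gives ``UNPAIRED``.
    """
    if base_loop is None or base_receptor is None:
        return PairClass.UNPAIRED
    for b in (base_loop, base_receptor):
        if b not in RNA_BASES:
            raise ValueError(f"not an RNA base: {b!r}")
    pair = (base_loop, base_receptor)
    if pair in _WC:
        return PairClass.WATSON_CRICK
    if pair in _WOBBLE:
        return PairClass.WOBBLE
    return PairClass.MISMATCH


def pairing_profile(variant: LoopReceptorVariant) -> PairingProfile:
    """Classify the five long-range pairs 8:22 ... 12:18 of *variant*.

    Also counts the G:C pairs in the long-range pairing, a determinant of
    tolerance to wobble pairs and mismatches at positions 11-12:19-18.
    """
    pairs = []
    gc = 0
    for loop_label, rec_label in PAIR_MAP:
        a = variant.residues.get(loop_label)
        b = variant.residues.get(rec_label)
        cls = classify_pair(a, b)
        if cls is PairClass.WATSON_CRICK and {a, b} == {"G", "C"}:
            gc += 1
        pairs.append(((loop_label, rec_label), cls))
    return PairingProfile(pairs=pairs, gc_count=gc)


def point_mutation_distance(a: LoopReceptorVariant, b: LoopReceptorVariant) -> int:
    """Number of positions at which two signatures differ.

    A residue facing a deletion/absence counts as one mutation, so del17 and
    insertion contexts are one point mutation away from their parents.
    """
    labels = set(a.residues) | set(b.residues)
    return sum(1 for l in labels if a.residues.get(l) != b.residues.get(l))


def family_components(
    variants: Sequence[LoopReceptorVariant], max_distance: int = 2
) -> list[list[str]]:
    """Group variants into sequence families by single-linkage at
    ``point_mutation_distance <= max_distance``.

    Returns families as lists of variant ids, largest family first; ties are
    broken by the lexicographically smallest member id. The output is a
    partition of the input and invariant to input order.
    """
    if not variants:
        raise ValueError("family_components requires at least one variant")
    order = sorted(variants, key=lambda v: v.id)
    parent = list(range(len(order)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            if point_mutation_distance(order[i], order[j]) <= max_distance:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict[int, list[str]] = {}
    for i, v in enumerate(order):
        groups.setdefault(find(i), []).append(v.id)
    families = [sorted(g) for g in groups.values()]
    families.sort(key=lambda g: (-len(g), g[0]))
    return families


_DEGENERATE = {
    frozenset("AG"): "R",
    frozenset("CU"): "Y",
    frozenset("AU"): "W",
}

_EXPAND = {"A": "A", "C": "C", "G": "G", "U": "U", "R": "AG", "Y": "CU", "W": "AU"}


def _alignment_columns(alignment) -> list[list[Optional[str]]]:
    """Columns of a SignatureAlignment or of a list of equal-length strings."""
    if isinstance(alignment, SignatureAlignment):
        if not alignment.variants:
            raise ValueError("consensus of an empty alignment")
        return [alignment.column(l) for l in alignment.columns]
    rows = list(alignment)
    if not rows:
        raise ValueError("consensus of an empty alignment")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("aligned strings must have equal length")
    return [
        [None if r[i] == "-" else r[i] for r in rows] for i in range(len(rows[0]))
    ]


def consensus(
    alignment,
    threshold: float = 0.75,
    minor_floor: float = 0.10,
    gap_symbol: str = "-",
) -> str:
    """Per-column consensus with IUPAC degenerate codes.

    *alignment* is a :class:`SignatureAlignment` or a list of equal-length
    aligned strings ("-" = gap). A column emits its majority symbol when its
    frequency (among non-gap entries) reaches *threshold* (inclusive);
    otherwise the smallest degenerate code among R (A/G), Y (U/C), W (A/U)
    covering every base above *minor_floor*, falling back to N. Columns where
    gaps are the majority emit *gap_symbol*. Consensus strings themselves
    (which may contain degenerate symbols) are valid input, making the
    operation idempotent.
    """
    columns = _alignment_columns(alignment)
    n = len(columns[0]) if columns else 0
    out = []
    for col in columns:
        gaps = sum(1 for c in col if c is None)
        if gaps * 2 > n:
            out.append(gap_symbol)
            continue
        present = [c for c in col if c is not None]
        counts: dict[str, int] = {}
        for c in present:
            counts[c] = counts.get(c, 0) + 1
        total = len(present)
        top_sym, top_n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        if top_n / total >= threshold:
            out.append(top_sym)
            continue
        bases: set[str] = set()
        for sym, k in counts.items():
            if k / total >= minor_floor:
                bases.update(_EXPAND.get(sym, "N"))
        code = _DEGENERATE.get(frozenset(bases), "N")
        out.append(code)
    return "".join(out)


# ---------------------------------------------------------------------------
# FASTA I/O

def _variant_to_record(v: LoopReceptorVariant) -> SeqRecord:
    labels = ",".join(v.labels)
    desc = f"stem={v.stem_length_bp} source={v.source} labels={labels}"
    return SeqRecord(Seq(v.sequence()), id=v.id, description=desc)


def write_fasta(variants: Iterable[LoopReceptorVariant], path) -> None:
    """Write signatures as FASTA with stem/source/label metadata in headers."""
    SeqIO.write([_variant_to_record(v) for v in variants], path, "fasta")


def read_fasta(path) -> list[LoopReceptorVariant]:
    """Read signature FASTA written by :func:`write_fasta`.

    Headers carry ``stem=``, ``source=`` and ``labels=`` tokens; when
    ``labels=`` is absent the record must be a full 23-residue signature on
    the canonical labels.
    """
    variants = []
    for rec in SeqIO.parse(path, "fasta"):
        tokens = dict(
            t.split("=", 1) for t in rec.description.split()[1:] if "=" in t
        )
        base_id, stem_from_name, suffix = parse_variant_name(rec.id)
        stem = int(tokens.get("stem", stem_from_name))
        seq = str(rec.seq).upper().replace("T", "U")
        if "labels" in tokens:
            labels = tokens["labels"].split(",")
        else:
            labels = [str(i) for i in range(1, len(seq) + 1)]
        if len(labels) != len(seq):
            raise ValueError(
                f"{rec.id}: {len(labels)} labels for {len(seq)} residues"
            )
        variants.append(
            LoopReceptorVariant(
                id=rec.id,
                residues=dict(zip(labels, seq)),
                base_id=base_id,
                stem_length_bp=stem,
                variant_suffix=suffix,
                source=tokens.get("source", "natural"),
            )
        )
    return variants


def signature_report(
    variants: Sequence[LoopReceptorVariant],
    reference_id: Optional[str] = None,
    max_distance: int = 2,
) -> pd.DataFrame:
    """Tabulate family membership, pairing classes and distances.

    One row per variant: id, family index, G:C count in the long-range
    pairing, the class of each of the five pairs, and the point-mutation
    distance to *reference_id* (omitted when no reference is given).
    """
    families = family_components(variants, max_distance=max_distance)
    fam_of = {vid: i for i, fam in enumerate(families) for vid in fam}
    by_id = {v.id: v for v in variants}
    ref = by_id.get(reference_id) if reference_id else None
    if reference_id is not None and ref is None:
        raise ValueError(f"reference variant {reference_id!r} not in input")
    rows = []
    for v in variants:
        prof = pairing_profile(v)
        row: dict = {"id": v.id, "family": fam_of[v.id], "gc_count": prof.gc_count}
        for (lp, rp), cls in prof.pairs:
            row[f"pair_{lp}_{rp}"] = cls.value
        if ref is not None:
            row[f"dist_to_{reference_id}"] = point_mutation_distance(v, ref)
        rows.append(row)
    return pd.DataFrame(rows)
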