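"""Canonical data types and text-file readers/writers.

Chemical-protein association lists, ECFP-style fingerprint bit vectors and
BLAST tabular hits all arrive as plain TSV.  Identifiers (InChIKey for
chemicals, UniProt accession for proteins) are treated as opaque strings;
matrices are 0-based indexed internally and files always carry ids, never
indices.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import DataError, FormatError, ParseError, UnitError

ACTIVE = "active"
INACTIVE = "inactive"
AMBIGUOUS = "ambiguous"
LABELS = (ACTIVE, INACTIVE, AMBIGUOUS)

#: multiplicative factors converting a concentration unit to micromolar
_UNIT_TO_UM = {
    "um": 1.0,
    "µm": 1.0,
    "μm": 1.0,
    "micromolar": 1.0,
    "nm": 1e-3,
    "pm": 1e-6,
    "mm": 1e3,
    "m": 1e6,
}


@dataclass(frozen=True)
class EntityVocabulary:
    """Ordered set of unique entity identifiers with 0-based positions."""

    ids: tuple[str, ...]
    index: dict[str, int] = field(compare=False)

    @classmethod
    def from_ids(cls, ids: Iterable[str]) -> "EntityVocabulary":
        ordered = tuple(ids)
        index = {name: k for k, name in enumerate(ordered)}
        if len(index) != len(ordered):
            raise DataError("duplicate identifiers in vocabulary")
        if not ordered:
            raise DataError("vocabulary must contain at least one identifier")
        return cls(ids=ordered, index=index)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, name: str) -> bool:
        return name in self.index


@dataclass(frozen=True)
class InteractionTable:
    """Sparse bipartite chemical-protein associations with activity labels.

    ``records`` holds one aggregated (chemical id, protein id, label) triple
    per observed pair; ``observed_positive_set`` indexes the active pairs by
    (chemical index, protein index).
    """

    chemicals: EntityVocabulary
    proteins: EntityVocabulary
    records: tuple[tuple[str, str, str], ...]
    observed_positive_set: frozenset[tuple[int, int]]

    @classmethod
    def from_records(
        cls,
        records: Sequence[tuple[str, str, str]],
        chemicals: EntityVocabulary | None = None,
        proteins: EntityVocabulary | None = None,
    ) -> "InteractionTable":
        """Build a table from aggregated records, inferring vocabularies if absent."""
        if chemicals is None:
            seen: dict[str, None] = {}
            for c, _, _ in records:
                seen.setdefault(c)
            chemicals = EntityVocabulary.from_ids(seen) if seen else None
        if proteins is None:
            seen = {}
            for _, p, _ in records:
                seen.setdefault(p)
            proteins = EntityVocabulary.from_ids(seen) if seen else None
        if chemicals is None or proteins is None:
            raise DataError("cannot infer vocabularies from an empty record list")
        pairs: set[tuple[str, str]] = set()
        positives = set()
        for c, p, label in records:
            if label not in LABELS:
                raise DataError(f"unknown activity label {label!r}")
            if c not in chemicals or p not in proteins:
                raise DataError(f"record ({c!r}, {p!r}) outside the vocabularies")
            if (c, p) in pairs:
                raise DataError(f"duplicate pair ({c!r}, {p!r}) after aggregation")
            pairs.add((c, p))
            if label == ACTIVE:
                positives.add((chemicals.index[c], proteins.index[p]))
        return cls(
            chemicals=chemicals,
            proteins=proteins,
            records=tuple(records),
            observed_positive_set=frozenset(positives),
        )

    @property
    def n_chemicals(self) -> int:
        return len(self.chemicals)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def positives_by_chemical(self) -> dict[int, set[int]]:
        """Map chemical index -> set of active protein indices."""
        out: dict[int, set[int]] = {}
        for i, j in self.observed_positive_set:
            out.setdefault(i, set()).add(j)
        return out


@dataclass(frozen=True)
class FingerprintSet:
    """Per-chemical substructure bit sets (ECFP-style) of a fixed length."""

    vocabulary: EntityVocabulary
    n_bits: int
    bits: tuple[frozenset[int], ...]

    def __post_init__(self) -> None:
        if len(self.bits) != len(self.vocabulary):
            raise DataError("one bit set required per vocabulary entry")
        for s in self.bits:
            if s and (min(s) < 0 or max(s) >= self.n_bits):
                raise FormatError("bit position outside declared fingerprint length")


def ic50_to_micromolar(value_ug_per_l: float, molecular_weight: float) -> float:
    """Convert an IC50 in micrograms/litre to micromolar.

    With the molecular weight in g/mol the conversion is a plain division:
    (µg/L) / (g/mol) = µmol/L.
    """
    if molecular_weight <= 0:
        raise ValueError("molecular_weight must be positive")
    if value_ug_per_l < 0:
        raise ValueError("concentration must be nonnegative")
    return value_ug_per_l / molecular_weight


def _parse_ic50_um(value: str, unit: str, line_no: int) -> float:
    unit_key = unit.strip().lower()
    if unit_key not in _UNIT_TO_UM:
        raise UnitError(f"line {line_no}: unknown concentration unit {unit!r}")
    try:
        v = float(value)
    except ValueError as exc:
        raise ParseError(f"line {line_no}: bad IC50 value {value!r}") from exc
    return v * _UNIT_TO_UM[unit_key]


def read_entity_list(path) -> EntityVocabulary:
    """Read a one-id-per-line vocabulary file (fixes cold-start entities)."""
    with open(path) as handle:
        ids = [line.strip() for line in handle if line.strip()]
    return EntityVocabulary.from_ids(ids)


def write_entity_list(vocabulary: EntityVocabulary, path) -> None:
    with open(path, "w") as handle:
        for name in vocabulary.ids:
            handle.write(name + "\n")


def read_interactions(
    path,
    ic50_threshold: float = 10.0,
    chemicals: EntityVocabulary | None = None,
    proteins: EntityVocabulary | None = None,
) -> InteractionTable:
    """Read a chemical-protein association TSV and aggregate activity labels.

    Columns (with header): ``chemical_id``, ``protein_id``, then either
    ``label`` or ``ic50_value`` + ``ic50_unit``.  Per pair, records with
    IC50 at or below the threshold (in µM) vote active, records above vote
    inactive; a pair seen in both ranges is ambiguous.  Explicit labels (as
    from curated drug-target lists) vote for their class directly.  Passing
    vocabularies keeps entities that have no records (cold start) in the
    index.
    """
    if ic50_threshold <= 0:
        raise ValueError("ic50_threshold must be positive")
    votes: dict[tuple[str, str], set[str]] = {}
    chem_order: dict[str, None] = {}
    prot_order: dict[str, None] = {}
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            header = None
        if header is not None:
            cols = {name.strip(): k for k, name in enumerate(header)}
            if "chemical_id" not in cols or "protein_id" not in cols:
                raise ParseError("line 1: header must name chemical_id and protein_id")
            has_label = "label" in cols
            has_ic50 = "ic50_value" in cols and "ic50_unit" in cols
            if not has_label and not has_ic50:
                raise ParseError(
                    "line 1: need a label column or ic50_value + ic50_unit columns"
                )
            for line_no, row in enumerate(reader, start=2):
                if not row or (len(row) == 1 and not row[0].strip()):
                    continue
                try:
                    chem = row[cols["chemical_id"]].strip()
                    prot = row[cols["protein_id"]].strip()
                except IndexError as exc:
                    raise ParseError(f"line {line_no}: too few columns") from exc
                if not chem or not prot:
                    raise ParseError(f"line {line_no}: empty identifier")
                label_cell = row[cols["label"]].strip() if has_label and cols["label"] < len(row) else ""
                if label_cell:
                    if label_cell not in LABELS:
                        raise ParseError(f"line {line_no}: unknown label {label_cell!r}")
                    vote = {label_cell}
                elif has_ic50:
                    try:
                        value = row[cols["ic50_value"]]
                        unit = row[cols["ic50_unit"]]
                    except IndexError as exc:
                        raise ParseError(f"line {line_no}: too few columns") from exc
                    um = _parse_ic50_um(value, unit, line_no)
                    vote = {ACTIVE if um <= ic50_threshold else INACTIVE}
                else:
                    raise ParseError(f"line {line_no}: row carries neither label nor IC50")
                chem_order.setdefault(chem)
                prot_order.setdefault(prot)
                votes.setdefault((chem, prot), set()).update(vote)
    records = []
    for (chem, prot) in sorted(votes):
        classes = votes[(chem, prot)]
        if AMBIGUOUS in classes or (ACTIVE in classes and INACTIVE in classes):
            label = AMBIGUOUS
        elif ACTIVE in classes:
            label = ACTIVE
        else:
            label = INACTIVE
        records.append((chem, prot, label))
    if not records and chemicals is None and proteins is None:
        empty = EntityVocabulary(ids=(), index={})
        return InteractionTable(
            chemicals=empty, proteins=empty, records=(), observed_positive_set=frozenset()
        )
    if chemicals is None:
        chemicals = EntityVocabulary.from_ids(sorted(chem_order))
    if proteins is None:
        proteins = EntityVocabulary.from_ids(sorted(prot_order))
    return InteractionTable.from_records(records, chemicals, proteins)


def decode_hex_fingerprint(hex_string: str, n_bits: int) -> frozenset[int]:
    """Decode a hex bit-vector into set-bit positions, big-endian within each byte."""
    expected = (n_bits + 7) // 8 * 2
    if len(hex_string) != expected:
        raise FormatError(
            f"hex string of length {len(hex_string)} inconsistent with {n_bits} bits"
        )
    try:
        raw = bytes.fromhex(hex_string)
    except ValueError as exc:
        raise FormatError(f"invalid hex string {hex_string!r}") from exc
    bits = set()
    for byte_idx, byte in enumerate(raw):
        for offset in range(8):
            pos = byte_idx * 8 + offset
            if pos >= n_bits:
                break
            if byte & (0x80 >> offset):
                bits.add(pos)
    return frozenset(bits)


def encode_hex_fingerprint(bits: frozenset[int] | set[int], n_bits: int) -> str:
    """Inverse of :func:`decode_hex_fingerprint`."""
    n_bytes = (n_bits + 7) // 8
    raw = bytearray(n_bytes)
    for pos in bits:
        if pos < 0 or pos >= n_bits:
            raise FormatError(f"bit position {pos} outside declared length {n_bits}")
        raw[pos // 8] |= 0x80 >> (pos % 8)
    return raw.hex().upper()


def read_fingerprints(path) -> FingerprintSet:
    """Read a fingerprint TSV: id, bit length, hex-encoded bit vector."""
    ids: list[str] = []
    bit_sets: list[frozenset[int]] = []
    n_bits = None
    with open(path, newline="") as handle:
        for line_no, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise ParseError(f"line {line_no}: expected 3 columns, got {len(row)}")
            name, length_str, hex_str = row[0].strip(), row[1].strip(), row[2].strip()
            try:
                length = int(length_str)
            except ValueError as exc:
                raise ParseError(f"line {line_no}: bad bit length {length_str!r}") from exc
            if n_bits is None:
                n_bits = length
            elif length != n_bits:
                raise FormatError(
                    f"line {line_no}: bit length {length} differs from {n_bits}"
                )
            ids.append(name)
            bit_sets.append(decode_hex_fingerprint(hex_str, length))
    if n_bits is None:
        raise ParseError("fingerprint file is empty")
    return FingerprintSet(
        vocabulary=EntityVocabulary.from_ids(ids), n_bits=n_bits, bits=tuple(bit_sets)
    )


def write_fingerprints(fps: FingerprintSet, path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for name, bits in zip(fps.vocabulary.ids, fps.bits):
            writer.writerow([name, fps.n_bits, encode_hex_fingerprint(bits, fps.n_bits)])


def read_blast_tabular(path, evalue_threshold: float = 1e-5) -> list[tuple[str, str, float]]:
    """Parse 12-column BLAST tabular hits, filter by e-value, keep max bit score.

    Columns follow the standard tabular output: query, subject, %identity,
    alignment length, mismatches, gap opens, qstart, qend, sstart, send,
    evalue, bit score.  Hits with e-value above the threshold are dropped;
    duplicate (query, subject) hits keep the maximum bit score.
    """
    best: dict[tuple[str, str], float] = {}
    order: dict[tuple[str, str], None] = {}
    with open(path, newline="") as handle:
        for line_no, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if len(row) < 12:
                raise ParseError(f"line {line_no}: expected 12 columns, got {len(row)}")
            query, subject = row[0].strip(), row[1].strip()
            try:
                evalue = float(row[10])
                bitscore = float(row[11])
            except ValueError as exc:
                raise ParseError(f"line {line_no}: bad e-value or bit score") from exc
            if evalue > evalue_threshold:
                continue
            key = (query, subject)
            order.setdefault(key)
            best[key] = max(best.get(key, float("-inf")), bitscore)
    return [(q, s, best[(q, s)]) for (q, s) in order]


def self_bit_scores(hits: Iterable[tuple[str, str, float]]) -> dict[str, float]:
    """Extract self-query bit scores d_bit(p, p) from a hit list."""
    return {q: score for q, s, score in hits if q == s}


def write_predictions(scores: Sequence[tuple], path) -> None:
    """Write ranked predictions as TSV, sorted by chemical id then rank.

    Each entry is (chemical id, protein id, raw score, calibrated score or
    None, rank).  Output is byte-identical for identical input.
    """
    rows = sorted(scores, key=lambda rec: (rec[0], rec[4]))
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["chemical_id", "protein_id", "raw_score", "calibrated_score", "rank"])
        for chem, prot, raw, calibrated, rank in rows:
            writer.writerow(
                [
                    chem,
                    prot,
                    format(float(raw), ".10g"),
                    "NA" if calibrated is None else format(float(calibrated), ".10g"),
                    int(rank),
                ]
            )


def read_predictions(path) -> list[tuple[str, str, float, float | None, int]]:
    """Inverse of :func:`write_predictions`."""
    out = []
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return out
        for line_no, row in enumerate(reader, start=2):
            if len(row) < 5:
                raise ParseError(f"line {line_no}: expected 5 columns")
            calibrated = None if row[3] == "NA" else float(row[3])
            out.append((row[0], row[1], float(row[2]), calibrated, int(row[4])))
    return out


def write_interactions(table: InteractionTable, path) -> None:
    """Write an aggregated association table with explicit labels."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["chemical_id", "protein_id", "label"])
        for chem, prot, label in table.records:
            writer.writerow([chem, prot, label])
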