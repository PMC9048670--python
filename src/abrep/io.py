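"""Repertoire input/output and the core in-memory model.

Reads IMGT-numbered antibody repertoires from two on-disk dialects:

* OAS-style CSV — first line a JSON object of study metadata, then CSV rows
  whose numbering is either a JSON map (flat ``position -> residue`` or nested
  ``region -> position -> residue``) in a ``numbering``/``anarci_numbering``
  column, or flat per-position columns named by IMGT labels.
* AIRR rearrangement TSV — standard column names; numbering taken from an
  IMGT-gapped ``sequence_alignment_aa`` or from per-position columns.

Numbered residues are authoritative: CDR strings stored in files are advisory
and recomputed from the numbering on load, with discrepancies logged.  Rows
with unparseable numbering or out-of-range positions are skipped per record
and counted in the load summary, never fatal.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .imgt import ImgtPosition, PositionParseError, extract_cdrs, parse_position, region_of

logger = logging.getLogger(__name__)

__all__ = [
    "StudyMetadata",
    "NumberedSequence",
    "Repertoire",
    "LoadSummary",
    "FormatError",
    "gene_of",
    "allele_of",
    "read_oas_csv",
    "write_oas_csv",
    "read_airr_tsv",
    "write_hits_table",
    "write_profile",
    "read_profile",
    "write_profile_store",
    "read_profile_store",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

PROFILE_FORMAT = "abrep-profile"
PROFILE_STORE_FORMAT = "abrep-profile-store"
PROFILE_VERSION = 1

_CHAIN_WORDS = {"HEAVY": "H", "KAPPA": "K", "LAMBDA": "L", "H": "H", "K": "K", "L": "L"}
_CALL_CHAIN_RE = re.compile(r"^IG([HKL])[VDJ]")


class FormatError(ValueError):
    """A repertoire file does not match any supported representation."""


def gene_of(call: str) -> str:
    """Gene-level part of a V/J call: text before ``*`` of the first assignment.

    Calls carrying multiple comma-separated assignments use the first.
    """
    first = call.split(",")[0].strip()
    return first.split("*")[0]


def allele_of(call: str) -> str:
    """Allele-level form (full ``GENE*NN`` string) of the first assignment."""
    return call.split(",")[0].strip()


@dataclass
class StudyMetadata:
    """Descriptive metadata of one study (one OAS unit)."""

    study_id: str
    species: str = ""
    chain: str = "H"
    disease: Optional[str] = None
    vaccine: Optional[str] = None
    b_source: Optional[str] = None
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValueError("study_id must be non-empty")
        if self.chain not in ("H", "K", "L"):
            raise ValueError(f"chain must be H, K or L, got {self.chain!r}")

    def to_dict(self) -> dict:
        d = {
            "study_id": self.study_id,
            "species": self.species,
            "chain": self.chain,
            "disease": self.disease,
            "vaccine": self.vaccine,
            "b_source": self.b_source,
        }
        d.update(self.extra)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyMetadata":
        d = dict(d)
        study_id = str(d.pop("study_id", "") or d.pop("Run", "") or d.pop("study", ""))
        species = str(d.pop("species", d.pop("Species", "")) or "")
        chain_raw = str(d.pop("chain", d.pop("Chain", "H")) or "H")
        chain = _CHAIN_WORDS.get(chain_raw.upper())
        if chain is None:
            raise FormatError(f"unrecognized chain designation: {chain_raw!r}")
        disease = d.pop("disease", d.pop("Disease", None)) or None
        vaccine = d.pop("vaccine", d.pop("Vaccine", None)) or None
        b_source = d.pop("b_source", d.pop("BSource", None)) or None
        extra = {k: str(v) for k, v in d.items() if v is not None}
        return cls(study_id, species, chain, disease, vaccine, b_source, extra)


@dataclass
class NumberedSequence:
    """One IMGT-numbered antibody chain.

    ``residues`` maps :class:`~abrep.imgt.ImgtPosition` to one-letter amino
    acids (``X`` tolerated).  CDR strings are derived from the numbering on
    construction and are therefore always internally consistent.
    """

    seq_id: str
    study_id: str
    chain: str
    residues: dict[ImgtPosition, str]
    v_call: str
    j_call: str
    raw_sequence: Optional[str] = None
    cdr1: str = field(init=False)
    cdr2: str = field(init=False)
    cdr3: str = field(init=False)

    def __post_init__(self) -> None:
        if self.chain not in ("H", "K", "L"):
            raise ValueError(f"chain must be H, K or L, got {self.chain!r}")
        for pos, res in self.residues.items():
            if res not in _VALID_RESIDUES:
                raise ValueError(f"invalid residue {res!r} at {pos} in {self.seq_id}")
        for call in (self.v_call, self.j_call):
            m = _CALL_CHAIN_RE.match(gene_of(call)) if call else None
            if m and m.group(1) != self.chain:
                raise ValueError(
                    f"{self.seq_id}: call {call!r} inconsistent with chain {self.chain}"
                )
        self.cdr1, self.cdr2, self.cdr3 = extract_cdrs(self.residues)

    @property
    def v_gene(self) -> str:
        return gene_of(self.v_call)

    @property
    def j_gene(self) -> str:
        return gene_of(self.j_call)

    def sorted_positions(self) -> list[ImgtPosition]:
        return sorted(self.residues, key=ImgtPosition.sort_key)

    def sequence(self) -> str:
        """Ungapped amino-acid string in IMGT order."""
        return "".join(self.residues[p] for p in self.sorted_positions())


@dataclass
class LoadSummary:
    rows_read: int = 0
    sequences_loaded: int = 0
    rows_skipped: int = 0
    messages: list[str] = field(default_factory=list)


@dataclass
class Repertoire:
    """One study's sequences plus its metadata."""

    metadata: StudyMetadata
    sequences: list[NumberedSequence] = field(default_factory=list)
    load_summary: Optional[LoadSummary] = None

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)


# ---------------------------------------------------------------------------
# raw-sequence numbering seam
#
# Assigning IMGT numbers to a raw amino-acid string requires a germline
# aligner, which this package does not ship.  Callers with such an engine
# (e.g. an ANARCI wrapper) can register it here; everything downstream only
# needs the NumberedSequence contract.

_numbering_hook = None


def set_numbering_hook(hook) -> None:
    """Register ``hook(raw_sequence, v_call, j_call, chain) -> NumberedSequence``."""
    global _numbering_hook
    _numbering_hook = hook


def number_raw_sequence(
    raw_sequence: str, v_call: str = "", j_call: str = "", chain: str = "H"
) -> NumberedSequence:
    """Number a raw sequence through the registered hook.

    Without a registered hook this refuses: supply pre-numbered records
    (OAS-style CSV or AIRR TSV) or register an IMGT numbering engine with
    :func:`set_numbering_hook`.
    """
    if _numbering_hook is None:
        raise NotImplementedError(
            "raw (un-numbered) sequences need an IMGT numbering engine; none is "
            "bundled. Provide pre-numbered input or register one via "
            "abrep.io.set_numbering_hook()."
        )
    return _numbering_hook(raw_sequence, v_call, j_call, chain)


# ---------------------------------------------------------------------------
# numbering representations


def _parse_numbering_json(blob: str) -> dict[ImgtPosition, str]:
    data = json.loads(blob)
    if not isinstance(data, dict):
        raise PositionParseError("numbering JSON is not an object")
    # nested region -> position -> residue, or flat position -> residue
    if data and all(isinstance(v, dict) for v in data.values()):
        flat: dict[str, str] = {}
        for inner in data.values():
            flat.update(inner)
    else:
        flat = data
    residues: dict[ImgtPosition, str] = {}
    for label, res in flat.items():
        residues[parse_position(label)] = str(res).upper()
    return residues


def _positions_from_header(names: Sequence[str]) -> dict[str, ImgtPosition]:
    """Header columns that parse as IMGT labels, e.g. '1'..'128', '111A'."""
    out: dict[str, ImgtPosition] = {}
    for name in names:
        if not name or not name[0].isdigit():
            continue
        try:
            out[name] = parse_position(name)
        except PositionParseError:
            continue
    return out


def _residues_from_gapped(aligned: str) -> dict[ImgtPosition, str]:
    """IMGT-gapped alignment string: character i maps to position i+1."""
    if len(aligned) > 128:
        raise PositionParseError(
            f"gapped alignment longer than 128 ({len(aligned)}); insertions "
            "require per-position columns"
        )
    residues: dict[ImgtPosition, str] = {}
    for i, ch in enumerate(aligned):
        if ch in ".-":
            continue
        residues[ImgtPosition(i + 1)] = ch.upper()
    return residues


def _check_stored_cdrs(row: dict, seq: NumberedSequence, where: str) -> None:
    for col, recomputed in (("cdr1", seq.cdr1), ("cdr2", seq.cdr2), ("cdr3", seq.cdr3)):
        stored = row.get(col) or row.get(f"{col}_aa") or ""
        if stored and stored.upper() != recomputed:
            logger.warning(
                "%s: stored %s %r disagrees with numbering-derived %r; using derived",
                where, col, stored, recomputed,
            )


# ---------------------------------------------------------------------------
# readers


def read_oas_csv(path) -> Repertoire:
    """Read an OAS-style CSV unit file (JSON metadata line + data rows)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        first = fh.readline()
        try:
            meta_raw = json.loads(first)
            if not isinstance(meta_raw, dict):
                raise ValueError
        except ValueError:
            raise FormatError(f"{path}, line 1: expected a JSON metadata object") from None
        metadata = StudyMetadata.from_dict(meta_raw)
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        json_col = next(
            (c for c in ("numbering", "anarci_numbering", "imgt_numbering") if c in header),
            None,
        )
        pos_cols = _positions_from_header(header)
        if json_col is None and not pos_cols:
            raise FormatError(
                f"{path}, line 2: no recognizable IMGT numbering representation "
                "(need a numbering JSON column or per-position columns)"
            )
        summary = LoadSummary()
        sequences: list[NumberedSequence] = []
        for lineno, row in enumerate(reader, start=3):
            summary.rows_read += 1
            seq_id = row.get("sequence_id") or row.get("seq_id") or f"row{lineno}"
            try:
                if json_col is not None:
                    residues = _parse_numbering_json(row[json_col])
                else:
                    residues = {
                        pos: row[name].upper()
                        for name, pos in pos_cols.items()
                        if row.get(name) and row[name] not in ".-"
                    }
                seq = NumberedSequence(
                    seq_id=seq_id,
                    study_id=metadata.study_id,
                    chain=metadata.chain,
                    residues=residues,
                    v_call=row.get("v_call", ""),
                    j_call=row.get("j_call", ""),
                )
            except (PositionParseError, ValueError, KeyError) as exc:
                summary.rows_skipped += 1
                msg = f"{path}, line {lineno}: skipped ({exc})"
                summary.messages.append(msg)
                logger.warning(msg)
                continue
            _check_stored_cdrs(row, seq, f"{path}, line {lineno}")
            sequences.append(seq)
            summary.sequences_loaded += 1
    return Repertoire(metadata, sequences, summary)


def read_airr_tsv(path, metadata: StudyMetadata) -> Repertoire:
    """Read an AIRR rearrangement TSV under externally supplied metadata."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in ("sequence_id", "v_call", "j_call") if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required AIRR columns: {', '.join(missing)}")
        pos_cols = _positions_from_header(header)
        if "sequence_alignment_aa" not in header and not pos_cols:
            raise FormatError(
                f"{path}: need sequence_alignment_aa or per-position numbering columns"
            )
        summary = LoadSummary()
        sequences: list[NumberedSequence] = []
        seen_ids: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            summary.rows_read += 1
            seq_id = row["sequence_id"]
            if seq_id in seen_ids:
                logger.warning("%s, line %d: duplicate sequence_id %r kept", path, lineno, seq_id)
            seen_ids.add(seq_id)
            try:
                if pos_cols:
                    residues = {
                        pos: row[name].upper()
                        for name, pos in pos_cols.items()
                        if row.get(name) and row[name] not in ".-"
                    }
                else:
                    residues = _residues_from_gapped(row["sequence_alignment_aa"])
                seq = NumberedSequence(
                    seq_id=seq_id,
                    study_id=metadata.study_id,
                    chain=metadata.chain,
                    residues=residues,
                    v_call=row.get("v_call", ""),
                    j_call=row.get("j_call", ""),
                )
            except (PositionParseError, ValueError, KeyError) as exc:
                summary.rows_skipped += 1
                msg = f"{path}, line {lineno}: skipped ({exc})"
                summary.messages.append(msg)
                logger.warning(msg)
                continue
            _check_stored_cdrs(row, seq, f"{path}, line {lineno}")
            sequences.append(seq)
            summary.sequences_loaded += 1
    return Repertoire(metadata, sequences, summary)


# ---------------------------------------------------------------------------
# writers


def write_oas_csv(rep: Repertoire, path) -> None:
    """Write a repertoire as an OAS-style CSV; round-trips through read_oas_csv."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write(json.dumps(rep.metadata.to_dict(), sort_keys=True) + "\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["sequence_id", "v_call", "j_call", "numbering", "cdr1", "cdr2", "cdr3"])
        for seq in rep.sequences:
            numbering: dict[str, dict[str, str]] = {}
            for pos in seq.sorted_positions():
                numbering.setdefault(region_of(pos), {})[pos.label] = seq.residues[pos]
            writer.writerow(
                [
                    seq.seq_id,
                    seq.v_call,
                    seq.j_call,
                    json.dumps(numbering),
                    seq.cdr1,
                    seq.cdr2,
                    seq.cdr3,
                ]
            )


HITS_COLUMNS = [
    "query_id",
    "seq_id",
    "study_id",
    "disease",
    "vaccine",
    "v_call",
    "j_call",
    "cdr3",
    "cdr3_mismatches",
    "identity",
    "imgt_aligned_row",
]


def write_hits_table(hits, path, alignment=None) -> None:
    """Write search hits as TSV with a stable column order.

    ``alignment`` may be the table from :func:`abrep.retrieval.align_hits_imgt`;
    when given, each hit's gapped row is included, otherwise the column is
    left empty.  Missing metadata renders as empty cells.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(HITS_COLUMNS)
        for hit in hits:
            row_str = ""
            if alignment is not None and hit.seq_id in alignment.index:
                # .loc[[id]] stays a frame even when the query row shares the id
                row_str = "".join(alignment.loc[[hit.seq_id]].iloc[-1])
            writer.writerow(
                [
                    hit.query_id,
                    hit.seq_id,
                    hit.study_id,
                    hit.disease or "",
                    hit.vaccine or "",
                    hit.v_call,
                    hit.j_call,
                    hit.cdr3,
                    hit.cdr3_mismatches,
                    f"{hit.identity:.6f}",
                    row_str,
                ]
            )


# ---------------------------------------------------------------------------
# profile store


def write_profile(profile, path) -> None:
    """Serialize one gene/allele profile as versioned JSON."""
    payload = {"format": PROFILE_FORMAT, "version": PROFILE_VERSION, "profile": profile.to_dict()}
    Path(path).write_text(json.dumps(payload, sort_keys=True), encoding="utf-8")


def read_profile(path):
    from .profiling import GeneProfile

    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format") != PROFILE_FORMAT or payload.get("version") != PROFILE_VERSION:
        raise FormatError(
            f"{path}: not a version-{PROFILE_VERSION} {PROFILE_FORMAT} file "
            f"(found format={payload.get('format')!r} version={payload.get('version')!r})"
        )
    return GeneProfile.from_dict(payload["profile"])


def write_profile_store(store, path) -> None:
    """Serialize a collection of profiles (a ProfileStore) as versioned JSON."""
    payload = {
        "format": PROFILE_STORE_FORMAT,
        "version": PROFILE_VERSION,
        "profiles": [p.to_dict() for p in store],
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True), encoding="utf-8")


def read_profile_store(path):
    from .profiling import GeneProfile, ProfileStore

    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format") != PROFILE_STORE_FORMAT or payload.get("version") != PROFILE_VERSION:
        raise FormatError(
            f"{path}: not a version-{PROFILE_VERSION} {PROFILE_STORE_FORMAT} file "
            f"(found format={payload.get('format')!r} version={payload.get('version')!r})"
        )
    return ProfileStore([GeneProfile.from_dict(d) for d in payload["profiles"]])
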