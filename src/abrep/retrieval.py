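"""k-mer indexed retrieval of similar antibody sequences.

CDR3s are bucketed by length and indexed by their k-mers (k=5 by default).
For a query CDR3 of length L, any indexed CDR3 of the same length within one
substitution shares at least one k-mer with it whenever L >= 2k (pigeonhole:
L - k + 1 > k surviving k-mers after one substitution), so candidate
generation is lossless at the default tolerance of one mismatch;
shorter CDR3s live in exhaustive-scan buckets.  Candidates are always
verified by Hamming distance, so the index can never return a false
positive.

Three search modes share the machinery:

* ``cdr3`` — same CDR3 length, Hamming distance <= max_mismatches (default 1);
* ``variable`` — the CDR3 rule plus matching CDR1/CDR2 (identical strings by
  default, or same length under the relaxed mode) and the same chain type;
* ``clonotype`` — same gene-level V call and identical CDR3 string; allele
  differences do not block a clonotype match.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .imgt import ImgtPosition
from .io import (
    FormatError,
    NumberedSequence,
    Repertoire,
    StudyMetadata,
    gene_of,
)

__all__ = [
    "SearchHit",
    "KmerIndex",
    "hamming",
    "build_index",
    "search_cdr3",
    "search_variable",
    "search_clonotype",
    "align_hits_imgt",
    "write_alignment",
    "summarize_hits_by_metadata",
    "save_index",
    "load_index",
]

INDEX_FORMAT = "abrep-kmer-index"
INDEX_VERSION = 1

GAP = "-"

#: reference to an indexed sequence: (study_id, seq_id)
Ref = tuple[str, str]


def hamming(a: str, b: str) -> int:
    """Substitution distance between equal-length strings.

    ``X`` (ambiguous residue) counts as a mismatch against everything,
    including another ``X``.
    """
    if len(a) != len(b):
        raise ValueError(f"hamming requires equal lengths ({len(a)} vs {len(b)})")
    return sum(1 for x, y in zip(a, b) if x != y or x == "X" or y == "X")


def identity_over_shared(q: NumberedSequence, hit: NumberedSequence) -> float:
    """Fraction of agreeing residues over IMGT positions present in both."""
    shared = q.residues.keys() & hit.residues.keys()
    if not shared:
        return 0.0
    agree = sum(
        1
        for p in shared
        if q.residues[p] == hit.residues[p] and q.residues[p] != "X"
    )
    return agree / len(shared)


@dataclass
class SearchHit:
    """One retrieved sequence with its distance to the query."""

    query_id: str
    seq_id: str
    study_id: str
    species: str
    disease: Optional[str]
    vaccine: Optional[str]
    v_call: str
    j_call: str
    cdr3: str
    cdr3_mismatches: int
    identity: float
    match_kind: str  # variable | cdr3 | clonotype

    def sort_key(self) -> tuple:
        return (self.cdr3_mismatches, -self.identity, self.seq_id, self.study_id)


class KmerIndex:
    """Length-bucketed k-mer index over CDR3s with clonotype side-tables."""

    def __init__(self, k: int = 5) -> None:
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.postings: dict[tuple[int, str], set[Ref]] = defaultdict(set)
        self.short_buckets: dict[int, set[Ref]] = defaultdict(set)
        self.by_length: dict[int, set[Ref]] = defaultdict(set)
        self.clonotypes: dict[tuple[str, str], set[Ref]] = defaultdict(set)
        self.store: dict[Ref, tuple[NumberedSequence, StudyMetadata]] = {}
        self._metadata: dict[str, StudyMetadata] = {}

    def __len__(self) -> int:
        return len(self.store)

    def add_repertoire(self, rep: Repertoire) -> None:
        self._metadata[rep.metadata.study_id] = rep.metadata
        for seq in rep.sequences:
            self.add_sequence(seq, rep.metadata)

    def add_sequence(self, seq: NumberedSequence, metadata: StudyMetadata) -> None:
        ref: Ref = (seq.study_id, seq.seq_id)
        self.store[ref] = (seq, metadata)
        cdr3 = seq.cdr3
        if not cdr3:
            return
        L = len(cdr3)
        self.by_length[L].add(ref)
        if L >= self.k:
            for i in range(L - self.k + 1):
                self.postings[(L, cdr3[i : i + self.k])].add(ref)
        if L < 2 * self.k:
            self.short_buckets[L].add(ref)
        self.clonotypes[(seq.v_gene, cdr3)].add(ref)

    def candidates(self, cdr3: str, max_mismatches: int) -> set[Ref]:
        """Candidate refs in the query's length bucket.

        Falls back to the whole length bucket when the pigeonhole guarantee
        (L - k + 1 > k * max_mismatches) does not hold, so verification by
        Hamming distance stays exhaustive-equivalent at any tolerance.
        """
        L = len(cdr3)
        if L - self.k + 1 <= self.k * max_mismatches:
            return set(self.by_length.get(L, ()))
        refs: set[Ref] = set()
        for i in range(L - self.k + 1):
            refs |= self.postings.get((L, cdr3[i : i + self.k]), set())
        refs |= self.short_buckets.get(L, set())
        return refs

    def resolve(self, ref: Ref) -> tuple[NumberedSequence, StudyMetadata]:
        return self.store[ref]


def build_index(reps: Iterable[Repertoire], k: int = 5) -> KmerIndex:
    """Index every sequence of every repertoire; order-independent content."""
    idx = KmerIndex(k=k)
    for rep in reps:
        idx.add_repertoire(rep)
    return idx


def _make_hit(
    idx: KmerIndex,
    ref: Ref,
    query_id: str,
    mismatches: int,
    identity: float,
    match_kind: str,
) -> SearchHit:
    seq, meta = idx.resolve(ref)
    return SearchHit(
        query_id=query_id,
        seq_id=seq.seq_id,
        study_id=seq.study_id,
        species=meta.species,
        disease=meta.disease,
        vaccine=meta.vaccine,
        v_call=seq.v_call,
        j_call=seq.j_call,
        cdr3=seq.cdr3,
        cdr3_mismatches=mismatches,
        identity=identity,
        match_kind=match_kind,
    )


def search_cdr3(
    idx: KmerIndex,
    query_cdr3: str,
    max_mismatches: int = 1,
    query_id: str = "query",
) -> list[SearchHit]:
    """All indexed sequences whose CDR3 matches the query's length within
    ``max_mismatches`` substitutions.

    For a bare CDR3 query the reported identity is CDR3-local:
    ``(L - mismatches) / L``.
    """
    if not query_cdr3:
        raise ValueError("query CDR3 must be non-empty")
    L = len(query_cdr3)
    hits = []
    for ref in idx.candidates(query_cdr3, max_mismatches):
        seq, _ = idx.resolve(ref)
        d = hamming(query_cdr3, seq.cdr3)
        if d <= max_mismatches:
            hits.append(_make_hit(idx, ref, query_id, d, (L - d) / L, "cdr3"))
    hits.sort(key=SearchHit.sort_key)
    return hits


def search_variable(
    idx: KmerIndex,
    q: NumberedSequence,
    cdr12_mode: str = "identical",
    max_mismatches: int = 1,
) -> list[SearchHit]:
    """Close full variable-region matches.

    Requires the query's chain type, same-length CDR1/CDR2 (identical strings
    under the default strict mode), and the CDR3 rule of :func:`search_cdr3`.
    Identity is computed over the IMGT positions shared by query and hit.
    """
    if cdr12_mode not in ("identical", "length_only"):
        raise ValueError(f"cdr12_mode must be 'identical' or 'length_only', got {cdr12_mode!r}")
    if not (q.cdr1 and q.cdr2 and q.cdr3):
        raise ValueError(
            f"query {q.seq_id!r} must carry all three CDRs "
            f"(got lengths {len(q.cdr1)}/{len(q.cdr2)}/{len(q.cdr3)})"
        )
    hits = []
    for ref in idx.candidates(q.cdr3, max_mismatches):
        seq, _ = idx.resolve(ref)
        if seq.chain != q.chain:
            continue
        d = hamming(q.cdr3, seq.cdr3)
        if d > max_mismatches:
            continue
        if cdr12_mode == "identical":
            if seq.cdr1 != q.cdr1 or seq.cdr2 != q.cdr2:
                continue
        else:
            if len(seq.cdr1) != len(q.cdr1) or len(seq.cdr2) != len(q.cdr2):
                continue
        hits.append(
            _make_hit(idx, ref, q.seq_id, d, identity_over_shared(q, seq), "variable")
        )
    hits.sort(key=SearchHit.sort_key)
    return hits


def search_clonotype(idx: KmerIndex, q: NumberedSequence) -> list[SearchHit]:
    """Members of the query's clonotype: same V-gene, identical CDR3.

    The V comparison is gene-level, so allele-differing sequences match.
    """
    v_gene = q.v_gene
    if not v_gene:
        raise ValueError(f"query {q.seq_id!r} has no parseable v_call ({q.v_call!r})")
    if not q.cdr3:
        raise ValueError(f"query {q.seq_id!r} has no CDR3")
    hits = []
    for ref in idx.clonotypes.get((v_gene, q.cdr3), set()):
        seq, _ = idx.resolve(ref)
        hits.append(
            _make_hit(idx, ref, q.seq_id, 0, identity_over_shared(q, seq), "clonotype")
        )
    hits.sort(key=SearchHit.sort_key)
    return hits


def align_hits_imgt(
    q: NumberedSequence, hits: Iterable[SearchHit], idx: KmerIndex
) -> pd.DataFrame:
    """IMGT-anchored multiple alignment of query and hits.

    Columns are the union of IMGT positions across all rows, in IMGT order;
    cells hold single residues with ``-`` at absent positions.  The query is
    the first row.
    """
    rows: list[tuple[str, dict[ImgtPosition, str]]] = [(q.seq_id, q.residues)]
    for hit in hits:
        seq, _ = idx.resolve((hit.study_id, hit.seq_id))
        rows.append((seq.seq_id, seq.residues))
    columns = sorted(
        {p for _, residues in rows for p in residues}, key=ImgtPosition.sort_key
    )
    table = pd.DataFrame(
        [[residues.get(p, GAP) for p in columns] for _, residues in rows],
        index=[rid for rid, _ in rows],
        columns=[p.label for p in columns],
    )
    return table


def write_alignment(table: pd.DataFrame, path) -> None:
    """Write an alignment table as gapped FASTA with a position header line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# positions\t" + "\t".join(table.columns) + "\n")
        for rid, row in table.iterrows():
            fh.write(f">{rid}\n{''.join(row)}\n")


_METADATA_FIELDS = ("study_id", "species", "disease", "vaccine", "b_source")
UNSPECIFIED = "unspecified"


def summarize_hits_by_metadata(hits: Iterable[SearchHit], field_name: str) -> pd.DataFrame:
    """Leading study themes among the hits.

    Counts hits and distinct studies per value of one metadata field; rows
    sorted by hit count descending, then value.  Missing/empty values are
    pooled under ``"unspecified"``.  ``b_source`` is accepted for symmetry
    with study metadata but is only populated when hits carry it.
    """
    if field_name not in _METADATA_FIELDS:
        raise ValueError(
            f"unknown metadata field {field_name!r}; expected one of {_METADATA_FIELDS}"
        )
    counts: dict[str, int] = defaultdict(int)
    studies: dict[str, set[str]] = defaultdict(set)
    for hit in hits:
        value = getattr(hit, field_name, None) or UNSPECIFIED
        counts[value] += 1
        studies[value].add(hit.study_id)
    records = [
        {"value": v, "hit_count": counts[v], "study_count": len(studies[v])}
        for v in counts
    ]
    records.sort(key=lambda r: (-r["hit_count"], r["value"]))
    return pd.DataFrame(records, columns=["value", "hit_count", "study_count"])


# ---------------------------------------------------------------------------
# persistence: the index file embeds the sequences and rebuilds the postings
# (building is deterministic, so a reload reproduces the postings exactly)


def _sequence_to_dict(seq: NumberedSequence) -> dict:
    return {
        "seq_id": seq.seq_id,
        "study_id": seq.study_id,
        "chain": seq.chain,
        "v_call": seq.v_call,
        "j_call": seq.j_call,
        "numbering": {p.label: r for p, r in sorted(seq.residues.items(), key=lambda kv: kv[0].sort_key())},
    }


def _sequence_from_dict(d: dict) -> NumberedSequence:
    from .imgt import parse_position

    return NumberedSequence(
        seq_id=d["seq_id"],
        study_id=d["study_id"],
        chain=d["chain"],
        residues={parse_position(label): r for label, r in d["numbering"].items()},
        v_call=d["v_call"],
        j_call=d["j_call"],
    )


def save_index(idx: KmerIndex, path) -> None:
    studies = {}
    for ref in sorted(idx.store):
        seq, meta = idx.store[ref]
        entry = studies.setdefault(
            meta.study_id, {"metadata": meta.to_dict(), "sequences": []}
        )
        entry["sequences"].append(_sequence_to_dict(seq))
    payload = {
        "format": INDEX_FORMAT,
        "version": INDEX_VERSION,
        "k": idx.k,
        "studies": [studies[sid] for sid in sorted(studies)],
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True), encoding="utf-8")


def load_index(path) -> KmerIndex:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format") != INDEX_FORMAT or payload.get("version") != INDEX_VERSION:
        raise FormatError(
            f"{path}: not a version-{INDEX_VERSION} {INDEX_FORMAT} file "
            f"(found format={payload.get('format')!r} version={payload.get('version')!r})"
        )
    idx = KmerIndex(k=payload["k"])
    for entry in payload["studies"]:
        meta = StudyMetadata.from_dict(entry["metadata"])
        rep = Repertoire(meta, [_sequence_from_dict(d) for d in entry["sequences"]])
        idx.add_repertoire(rep)
    return idx
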