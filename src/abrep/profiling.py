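"""Positional amino-acid diversity profiles per V/J germline group.

A profile describes, for every IMGT position of all sequences sharing one
V-gene/J-gene combination (or one allele combination), the observed residue
frequencies.  Statistics are computed per study first — frequencies, Shannon
entropy in bits, competition ranks of the residues by frequency — and only
then aggregated across studies with equal weight per study.  Computing within
studies and averaging across them mitigates the dominance of large studies
and study-specific biases: a study only contributes a (position, residue)
observation, and a position's statistics are never pooled over raw sequence
counts from different experiments.

A study's frequencies at a position enter a profile only when the study has
at least ``min_observations`` (default 100) sequences covering that position
within the group; positions below the threshold are dropped for that study.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy

from .imgt import ImgtPosition, parse_position, region_of
from .io import NumberedSequence, Repertoire, allele_of, gene_of

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileKey",
    "StudyPositionStats",
    "ResidueAggregate",
    "PositionProfile",
    "GeneProfile",
    "ProfileStore",
    "QueryAnnotation",
    "shannon_entropy",
    "rank_residues",
    "build_study_stats",
    "aggregate_profile",
    "annotate_query",
]

DEFAULT_MIN_OBSERVATIONS = 100
_FREQ_TOL = 1e-9


@dataclass(frozen=True)
class ProfileKey:
    """Identity of a profile group: chain + V group + J group at a resolution."""

    chain: str
    v_group: str
    j_group: str
    resolution: str  # "gene" | "allele"

    def __post_init__(self) -> None:
        if self.resolution not in ("gene", "allele"):
            raise ValueError(f"resolution must be 'gene' or 'allele', got {self.resolution!r}")
        for label, group in (("v_group", self.v_group), ("j_group", self.j_group)):
            stars = group.count("*")
            if self.resolution == "gene" and stars != 0:
                raise ValueError(f"gene-resolution {label} must not contain '*': {group!r}")
            if self.resolution == "allele" and stars != 1:
                raise ValueError(f"allele-resolution {label} needs exactly one '*': {group!r}")

    def __str__(self) -> str:
        return f"{self.chain}:{self.v_group}/{self.j_group}@{self.resolution}"


def shannon_entropy(freqs: Mapping[str, float]) -> float:
    """Shannon entropy, in bits, of a residue frequency distribution.

    Proportions must be non-negative and sum to 1 within 1e-9; zero
    proportions contribute nothing, and a single-residue distribution has
    entropy 0.
    """
    values = np.asarray(list(freqs.values()), dtype=float)
    if values.size == 0 or np.any(values < 0):
        raise ValueError("frequencies must be a non-empty map of non-negative proportions")
    total = values.sum()
    if abs(total - 1.0) > _FREQ_TOL:
        raise ValueError(f"frequencies must sum to 1 within {_FREQ_TOL}; got {total!r}")
    return float(_scipy_entropy(values, base=2))


def rank_residues(freqs: Mapping[str, float]) -> dict[str, int]:
    """Competition ranks of observed residues by descending frequency.

    Tied frequencies share the minimal rank (1, 1, 3, ...).  Only residues
    with positive proportion receive a rank.
    """
    observed = {res: p for res, p in freqs.items() if p > 0}
    if not observed:
        raise ValueError("no residue with positive proportion")
    values = np.array(list(observed.values()))
    ranks = {}
    for res, p in observed.items():
        ranks[res] = int(1 + np.sum(values > p))
    return ranks


def unobserved_rank(freqs: Mapping[str, float]) -> int:
    """Rank convention for a residue absent from a study: n_observed + 1."""
    return sum(1 for p in freqs.values() if p > 0) + 1


@dataclass
class StudyPositionStats:
    """One study's residue statistics at one IMGT position of one group."""

    study_id: str
    position: ImgtPosition
    counts: dict[str, int]
    n: int
    freqs: dict[str, float]
    entropy_bits: float
    ranks: dict[str, int]

    @classmethod
    def from_counts(cls, study_id: str, position: ImgtPosition, counts: Mapping[str, int]):
        counts = {res: int(c) for res, c in counts.items() if c > 0}
        n = sum(counts.values())
        freqs = {res: c / n for res, c in counts.items()}
        return cls(
            study_id=study_id,
            position=position,
            counts=counts,
            n=n,
            freqs=freqs,
            entropy_bits=shannon_entropy(freqs),
            ranks=rank_residues(freqs),
        )


def _group_of(seq: NumberedSequence, resolution: str) -> Optional[tuple[str, str]]:
    if resolution == "gene":
        v, j = seq.v_gene, seq.j_gene
        if v and j:
            return v, j
        return None
    v, j = allele_of(seq.v_call), allele_of(seq.j_call)
    if "*" in v and "*" in j:
        return v, j
    return None


def build_study_stats(
    rep: Repertoire,
    resolution: str = "gene",
    min_observations: int = DEFAULT_MIN_OBSERVATIONS,
) -> dict[ProfileKey, list[StudyPositionStats]]:
    """Per-position residue statistics of one study, grouped by profile key.

    Residue ``X`` (ambiguous call) is excluded from the counts.  A
    (group, position) record is retained only when its total observation
    count reaches ``min_observations``.
    """
    if min_observations < 1:
        raise ValueError("min_observations must be >= 1")
    counts: dict[ProfileKey, dict[ImgtPosition, dict[str, int]]] = defaultdict(
        lambda: defaultdict(lambda: defaultdict(int))
    )
    skipped = 0
    for seq in rep.sequences:
        group = _group_of(seq, resolution)
        if group is None:
            skipped += 1
            continue
        key = ProfileKey(seq.chain, group[0], group[1], resolution)
        for pos, res in seq.residues.items():
            if res == "X":
                continue
            counts[key][pos][res] += 1
    if skipped:
        logger.info("%s: %d sequences unresolvable at %s resolution", rep.metadata.study_id, skipped, resolution)
    out: dict[ProfileKey, list[StudyPositionStats]] = {}
    study_id = rep.metadata.study_id
    for key, per_pos in counts.items():
        records = [
            StudyPositionStats.from_counts(study_id, pos, c)
            for pos, c in per_pos.items()
            if sum(c.values()) >= min_observations
        ]
        if records:
            records.sort(key=lambda r: r.position.sort_key())
            out[key] = records
    return out


@dataclass
class ResidueAggregate:
    """Cross-study aggregate for one residue at one position."""

    rank_mean: float
    rank_median: float
    rank_std: float
    prop_mean: float
    prop_median: float
    prop_std: float
    n_studies_observed: int


@dataclass
class PositionProfile:
    """Cross-study aggregate at one IMGT position."""

    entropy_mean: float
    entropy_median: float
    entropy_std: float
    n_studies: int
    residues: dict[str, ResidueAggregate]
    study_freqs: dict[str, dict[str, float]]  # drill-down: study -> residue -> freq


def _agg(values: Sequence[float]) -> tuple[float, float, float]:
    arr = np.asarray(values, dtype=float)
    # population std: a single contributing study yields 0, not NaN
    return float(arr.mean()), float(np.median(arr)), float(arr.std(ddof=0))


@dataclass
class GeneProfile:
    """Aggregated positional diversity profile for one V/J group."""

    key: ProfileKey
    positions: dict[ImgtPosition, PositionProfile] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "key": {
                "chain": self.key.chain,
                "v_group": self.key.v_group,
                "j_group": self.key.j_group,
                "resolution": self.key.resolution,
            },
            "positions": {
                pos.label: {
                    "entropy_mean": pp.entropy_mean,
                    "entropy_median": pp.entropy_median,
                    "entropy_std": pp.entropy_std,
                    "n_studies": pp.n_studies,
                    "residues": {
                        res: vars(agg) for res, agg in sorted(pp.residues.items())
                    },
                    "study_freqs": pp.study_freqs,
                }
                for pos, pp in sorted(self.positions.items(), key=lambda kv: kv[0].sort_key())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneProfile":
        key = ProfileKey(**d["key"])
        positions = {}
        for label, pd_ in d["positions"].items():
            positions[parse_position(label)] = PositionProfile(
                entropy_mean=pd_["entropy_mean"],
                entropy_median=pd_["entropy_median"],
                entropy_std=pd_["entropy_std"],
                n_studies=pd_["n_studies"],
                residues={res: ResidueAggregate(**a) for res, a in pd_["residues"].items()},
                study_freqs={s: dict(f) for s, f in pd_["study_freqs"].items()},
            )
        return cls(key, positions)


def aggregate_profile(
    key: ProfileKey,
    stats: Iterable[StudyPositionStats],
    include_unobserved: bool = False,
) -> GeneProfile:
    """Aggregate per-study statistics of one profile group across studies.

    Every study carries equal weight regardless of its sequence count.  By
    default a residue's rank/proportion aggregates run over the studies that
    observed it (coverage recorded in ``n_studies_observed``); with
    ``include_unobserved`` studies covering the position but lacking the
    residue contribute rank ``n_observed + 1`` and proportion 0.
    """
    by_pos: dict[ImgtPosition, list[StudyPositionStats]] = defaultdict(list)
    for rec in stats:
        by_pos[rec.position].append(rec)
    if not by_pos:
        raise ValueError("aggregate_profile requires at least one study record")
    positions: dict[ImgtPosition, PositionProfile] = {}
    for pos, recs in by_pos.items():
        ent_mean, ent_med, ent_std = _agg([r.entropy_bits for r in recs])
        all_residues = sorted({res for r in recs for res in r.freqs})
        residues: dict[str, ResidueAggregate] = {}
        for res in all_residues:
            ranks, props = [], []
            observed = 0
            for r in recs:
                if res in r.freqs:
                    ranks.append(r.ranks[res])
                    props.append(r.freqs[res])
                    observed += 1
                elif include_unobserved:
                    ranks.append(unobserved_rank(r.freqs))
                    props.append(0.0)
            rank_mean, rank_med, rank_std = _agg(ranks)
            prop_mean, prop_med, prop_std = _agg(props)
            residues[res] = ResidueAggregate(
                rank_mean, rank_med, rank_std, prop_mean, prop_med, prop_std, observed
            )
        positions[pos] = PositionProfile(
            entropy_mean=ent_mean,
            entropy_median=ent_med,
            entropy_std=ent_std,
            n_studies=len(recs),
            residues=residues,
            study_freqs={r.study_id: dict(r.freqs) for r in recs},
        )
    return GeneProfile(key, positions)


class ProfileStore:
    """A keyed collection of :class:`GeneProfile` objects."""

    def __init__(self, profiles: Iterable[GeneProfile] = ()) -> None:
        self._profiles: dict[ProfileKey, GeneProfile] = {}
        for p in profiles:
            self.add(p)

    def add(self, profile: GeneProfile) -> None:
        self._profiles[profile.key] = profile

    def get(self, key: ProfileKey) -> Optional[GeneProfile]:
        return self._profiles.get(key)

    def __len__(self) -> int:
        return len(self._profiles)

    def __iter__(self):
        return iter(sorted(self._profiles.values(), key=lambda p: str(p.key)))

    def keys(self) -> list[ProfileKey]:
        return sorted(self._profiles, key=str)

    @classmethod
    def build(
        cls,
        reps: Iterable[Repertoire],
        resolution: str = "gene",
        min_observations: int = DEFAULT_MIN_OBSERVATIONS,
        include_unobserved: bool = False,
    ) -> "ProfileStore":
        """Build profiles for every V/J group present across ``reps``."""
        merged: dict[ProfileKey, list[StudyPositionStats]] = defaultdict(list)
        for rep in reps:
            for key, recs in build_study_stats(rep, resolution, min_observations).items():
                merged[key].extend(recs)
        return cls(
            aggregate_profile(key, recs, include_unobserved) for key, recs in merged.items()
        )


ANNOTATION_COLUMNS = [
    "position",
    "region",
    "query_residue",
    "rank_mean",
    "rank_median",
    "rank_std",
    "prop_mean",
    "prop_median",
    "prop_std",
    "entropy_mean",
    "entropy_median",
    "entropy_std",
    "n_studies",
    "flags",
]


@dataclass
class QueryAnnotation:
    """Per-position diversity annotation of one query sequence."""

    query_id: str
    key: ProfileKey
    resolution_requested: str
    notes: list[str]
    rows: list[dict]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=ANNOTATION_COLUMNS)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# profile_key\t{self.key}\n")
            fh.write(f"# resolution_requested\t{self.resolution_requested}\n")
            for note in self.notes:
                fh.write(f"# note\t{note}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _candidate_keys(q: NumberedSequence, resolution: str) -> list[ProfileKey]:
    keys = []
    if resolution == "allele":
        v, j = allele_of(q.v_call), allele_of(q.j_call)
        if "*" in v and "*" in j:
            keys.append(ProfileKey(q.chain, v, j, "allele"))
    keys.append(ProfileKey(q.chain, q.v_gene, q.j_gene, "gene"))
    return keys


def annotate_query(
    q: NumberedSequence, store: ProfileStore, resolution: str = "gene"
) -> QueryAnnotation:
    """Annotate a query with the aggregate statistics of its germline profile.

    The profile must match both V and J groups.  An allele-resolution request
    falls back to the gene-resolution profile, with a recorded note, when no
    allele profile matches.  Query positions absent from the profile, or
    residues never observed in it, are flagged rather than dropped.
    """
    if resolution not in ("gene", "allele"):
        raise ValueError(f"resolution must be 'gene' or 'allele', got {resolution!r}")
    attempted = _candidate_keys(q, resolution)
    profile = None
    notes: list[str] = []
    if resolution == "allele" and (not attempted or attempted[0].resolution != "allele"):
        notes.append("allele resolution requested but query calls carry no allele; using gene")
    for key in attempted:
        profile = store.get(key)
        if profile is not None:
            if resolution == "allele" and key.resolution == "gene" and not notes:
                notes.append(f"no allele-resolution profile; fell back to gene profile {key}")
            break
    if profile is None:
        raise LookupError(
            "no profile matches query "
            f"{q.seq_id!r}; attempted keys: {', '.join(str(k) for k in attempted)}"
        )
    rows = []
    for pos in q.sorted_positions():
        res = q.residues[pos]
        row = {c: None for c in ANNOTATION_COLUMNS}
        row.update(position=pos.label, region=region_of(pos), query_residue=res)
        flags = []
        pp = profile.positions.get(pos)
        if pp is None:
            flags.append("position_not_in_profile")
        else:
            row.update(
                entropy_mean=pp.entropy_mean,
                entropy_median=pp.entropy_median,
                entropy_std=pp.entropy_std,
                n_studies=pp.n_studies,
            )
            agg = pp.residues.get(res)
            if agg is None:
                flags.append("residue_unobserved")
            else:
                row.update(
                    rank_mean=agg.rank_mean,
                    rank_median=agg.rank_median,
                    rank_std=agg.rank_std,
                    prop_mean=agg.prop_mean,
                    prop_median=agg.prop_median,
                    prop_std=agg.prop_std,
                )
        row["flags"] = ";".join(flags)
        rows.append(row)
    return QueryAnnotation(q.seq_id, profile.key, resolution, notes, rows)
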