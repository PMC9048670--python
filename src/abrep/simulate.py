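"""Synthetic IMGT-numbered repertoires with known ground truth.

The generator emulates the statistical structure of public repertoire unit
files at desk scale: a handful of studies, each a set of sequences built from
toy germline V/J templates with a randomly sampled CDR3 junction and
independent per-position substitutions at a configurable rate.  The toy
germlines are fictitious high-numbered genes (IGHV901.., IGKJ901..) so that
chain-consistency checks behave as they would on real annotator output,
without impersonating real IMGT alleles.

Every simulated sequence's template, true substitutions and clonotype key are
recorded in a ground-truth sidecar so profiling and retrieval can be tested
against known answers.  All randomness flows from one seeded generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .imgt import ImgtPosition, cdr3_ladder
from .io import AMINO_ACIDS, NumberedSequence, Repertoire, StudyMetadata, gene_of

__all__ = [
    "GermlineTemplate",
    "SimulationConfig",
    "GroundTruth",
    "packaged_germlines",
    "simulate_repertoires",
    "spike_neighbors",
    "write_ground_truth",
]

_AA = np.array(list(AMINO_ACIDS))
_GERMLINE_SEED = 97531  # fixed: the toy germline set is a constant of the package


@dataclass(frozen=True)
class GermlineTemplate:
    """A toy germline segment: V covers IMGT 1-104, J covers 118-128."""

    name: str  # "IGHV901*01"-style
    chain: str
    segment: str  # "V" | "J"
    residues: dict[ImgtPosition, str]

    def __post_init__(self) -> None:
        numbers = sorted(p.number for p in self.residues)
        if self.segment == "V":
            if numbers != list(range(1, 105)):
                raise ValueError(f"V template {self.name} must cover positions 1-104")
        elif self.segment == "J":
            if numbers != list(range(118, 129)):
                raise ValueError(f"J template {self.name} must cover positions 118-128")
        else:
            raise ValueError(f"segment must be V or J, got {self.segment!r}")

    @property
    def gene(self) -> str:
        return gene_of(self.name)


def _random_protein(rng: np.random.Generator, length: int) -> list[str]:
    return [str(a) for a in rng.choice(_AA, size=length)]


def packaged_germlines() -> list[GermlineTemplate]:
    """The fixed toy germline set: 3 V genes x 2 alleles and 2 J genes for
    each of chains H and K.  Deterministic on every call.

    Anchors mimic real variable domains: V position 104 is the conserved
    Cys, J position 118 the conserved Trp (heavy) / Phe (kappa).
    """
    rng = np.random.default_rng(_GERMLINE_SEED)
    templates: list[GermlineTemplate] = []
    for chain in ("H", "K"):
        for g in (901, 902, 903):
            base = _random_protein(rng, 104)
            base[103] = "C"  # conserved 2nd-CYS at IMGT 104
            for allele, variant_pos in ((1, None), (2, 49)):
                residues = list(base)
                if variant_pos is not None:
                    old = residues[variant_pos]
                    alternatives = [a for a in AMINO_ACIDS if a != old]
                    residues[variant_pos] = alternatives[int(rng.integers(19))]
                templates.append(
                    GermlineTemplate(
                        name=f"IG{chain}V{g}*0{allele}",
                        chain=chain,
                        segment="V",
                        residues={
                            ImgtPosition(i + 1): res for i, res in enumerate(residues)
                        },
                    )
                )
        for g in (901, 902):
            residues = _random_protein(rng, 11)
            residues[0] = "W" if chain == "H" else "F"  # J-TRP / J-PHE at 118
            templates.append(
                GermlineTemplate(
                    name=f"IG{chain}J{g}*01",
                    chain=chain,
                    segment="J",
                    residues={
                        ImgtPosition(118 + i): res for i, res in enumerate(residues)
                    },
                )
            )
    return templates


_DEFAULT_CDR3_LENGTHS = {12: 0.15, 13: 0.2, 14: 0.2, 15: 0.2, 16: 0.15, 17: 0.1}
_DEFAULT_THEMES = [
    ("SARS-CoV-2", None),
    (None, "Influenza"),
    (None, None),
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic repertoire generator.

    ``mutation_rate`` is the independent per-position substitution
    probability applied to template-derived positions (V: 1-104, J:
    118-128); the CDR3 junction between them is sampled de novo, uniform
    over residues with the 105 Cys fixed, at a length drawn from
    ``cdr3_length_distribution``.
    """

    n_studies: int = 5
    sequences_per_study: int = 1000
    mutation_rate: float = 0.01
    cdr3_length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_CDR3_LENGTHS)
    )
    seed: int = 0
    chain: str = "H"
    species: str = "human"
    metadata_themes: list[tuple[Optional[str], Optional[str]]] = field(
        default_factory=lambda: list(_DEFAULT_THEMES)
    )
    allele_weights: Optional[dict[str, float]] = None  # name -> weight, default uniform

    def __post_init__(self) -> None:
        if self.n_studies < 1 or self.sequences_per_study < 1:
            raise ValueError("n_studies and sequences_per_study must be >= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        probs = np.array(list(self.cdr3_length_distribution.values()), dtype=float)
        if probs.size == 0 or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("cdr3_length_distribution must be probabilities summing to 1")
        if any(l < 1 for l in self.cdr3_length_distribution):
            raise ValueError("CDR3 lengths must be >= 1")
        if self.chain not in ("H", "K", "L"):
            raise ValueError("chain must be H, K or L")


@dataclass
class GroundTruth:
    """What the generator actually did, per sequence."""

    config: SimulationConfig
    records: dict[str, dict] = field(default_factory=dict)

    def clonotype_partition(self) -> dict[tuple[str, str], set[str]]:
        partition: dict[tuple[str, str], set[str]] = {}
        for seq_id, rec in self.records.items():
            key = (rec["clonotype"][0], rec["clonotype"][1])
            partition.setdefault(key, set()).add(seq_id)
        return partition


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "config": {
            "n_studies": truth.config.n_studies,
            "sequences_per_study": truth.config.sequences_per_study,
            "mutation_rate": truth.config.mutation_rate,
            "seed": truth.config.seed,
            "chain": truth.config.chain,
        },
        "records": truth.records,
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True), encoding="utf-8")


def _weighted_choice(rng: np.random.Generator, items: Sequence, weights=None):
    i = rng.choice(len(items), p=weights)
    return items[int(i)]


def simulate_repertoires(
    cfg: SimulationConfig,
    germlines: Optional[Iterable[GermlineTemplate]] = None,
) -> tuple[list[Repertoire], GroundTruth]:
    """Generate ``cfg.n_studies`` repertoires; identical seed, identical output."""
    templates = list(germlines) if germlines is not None else packaged_germlines()
    v_templates = sorted(
        (t for t in templates if t.segment == "V" and t.chain == cfg.chain),
        key=lambda t: t.name,
    )
    j_templates = sorted(
        (t for t in templates if t.segment == "J" and t.chain == cfg.chain),
        key=lambda t: t.name,
    )
    if not v_templates or not j_templates:
        raise ValueError(f"no V/J templates for chain {cfg.chain}")

    def weights(ts):
        if cfg.allele_weights is None:
            return None
        w = np.array([cfg.allele_weights.get(t.name, 0.0) for t in ts], dtype=float)
        if w.sum() <= 0:
            raise ValueError("allele_weights assign no mass to available templates")
        return w / w.sum()

    vw, jw = weights(v_templates), weights(j_templates)
    lengths = sorted(cfg.cdr3_length_distribution)
    length_probs = np.array([cfg.cdr3_length_distribution[l] for l in lengths])
    length_probs = length_probs / length_probs.sum()

    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth(cfg)
    repertoires: list[Repertoire] = []
    for s in range(cfg.n_studies):
        disease, vaccine = cfg.metadata_themes[s % len(cfg.metadata_themes)]
        meta = StudyMetadata(
            study_id=f"SIM{s:03d}",
            species=cfg.species,
            chain=cfg.chain,
            disease=disease,
            vaccine=vaccine,
            b_source="PBMC",
        )
        sequences: list[NumberedSequence] = []
        for i in range(cfg.sequences_per_study):
            v = _weighted_choice(rng, v_templates, vw)
            j = _weighted_choice(rng, j_templates, jw)
            residues = dict(v.residues)
            residues.update(j.residues)
            # mutate template-derived positions only
            mutated: list[str] = []
            if cfg.mutation_rate > 0:
                positions = sorted(residues, key=ImgtPosition.sort_key)
                hit = rng.random(len(positions)) < cfg.mutation_rate
                for pos, is_hit in zip(positions, hit):
                    if is_hit:
                        old = residues[pos]
                        alternatives = [a for a in AMINO_ACIDS if a != old]
                        residues[pos] = alternatives[int(rng.integers(19))]
                        mutated.append(pos.label)
            # CDR3 junction, de novo
            L = int(_weighted_choice(rng, lengths, length_probs))
            for pos in cdr3_ladder(L):
                residues[pos] = "C" if pos.number == 105 and pos.insertion == 0 else str(
                    rng.choice(_AA)
                )
            seq = NumberedSequence(
                seq_id=f"SIM{s:03d}_{i:06d}",
                study_id=meta.study_id,
                chain=cfg.chain,
                residues=residues,
                v_call=v.name,
                j_call=j.name,
            )
            sequences.append(seq)
            truth.records[seq.seq_id] = {
                "study_id": meta.study_id,
                "v_call": v.name,
                "j_call": j.name,
                "mutations": mutated,
                "clonotype": [v.gene, seq.cdr3],
            }
        repertoires.append(Repertoire(meta, sequences))
    return repertoires, truth


def spike_neighbors(
    q: NumberedSequence, n: int, cdr3_substitutions: int, seed: int
) -> list[NumberedSequence]:
    """``n`` copies of ``q``, each with exactly ``cdr3_substitutions`` random
    CDR3 substitutions at distinct positions, under fresh sequence ids."""
    cdr3_positions = sorted(
        (p for p in q.residues if 105 <= p.number <= 117), key=ImgtPosition.sort_key
    )
    if cdr3_substitutions < 0 or cdr3_substitutions > len(cdr3_positions):
        raise ValueError(
            f"cannot place {cdr3_substitutions} substitutions in a CDR3 of "
            f"length {len(cdr3_positions)}"
        )
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        residues = dict(q.residues)
        chosen = rng.choice(len(cdr3_positions), size=cdr3_substitutions, replace=False)
        for ci in sorted(int(c) for c in chosen):
            pos = cdr3_positions[ci]
            old = residues[pos]
            alternatives = [a for a in AMINO_ACIDS if a != old]
            residues[pos] = alternatives[int(rng.integers(19))]
        out.append(
            NumberedSequence(
                seq_id=f"{q.seq_id}_spike{i}",
                study_id=q.study_id,
                chain=q.chain,
                residues=residues,
                v_call=q.v_call,
                j_call=q.j_call,
            )
        )
    return out
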