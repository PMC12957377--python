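"""Synthetic data with the statistical structure of a longitudinal two-genotype
multi-omics study.

The generator emulates a serum proteome/metabolome cohort: two genotypes
(``WT`` vs ``MUT``) sampled at three ages with unbalanced group sizes,
longitudinal subjects with a shared random intercept, a small set of planted
genotype-effect analytes (stable disease markers, late-onset markers, and
age-correlated analytes), additive per-mixture batch shifts (the TMT-mixture
analog), and MCAR missingness. Abundances are generated directly on log2
scale. A :class:`GroundTruth` records every planted quantity so downstream
stages can be validated against a known answer.

A second generator, :func:`simulate_discrete_dag`, forward-samples small
discrete datasets from a known directed acyclic graph, giving the network
stage a recoverable ground truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import MultiOmicsDataset
from .network import Dag

PROTEIN_TERMS = ["protease", "lysosome", "muscle", "cytokine", "transport", "signaling"]
METABOLITE_TERMS = ["glycerophosphodiester", "sphingolipid", "phospholipid", "amino-acid"]


@dataclass(frozen=True)
class PlantedStable:
    """Genotype effect present at every timepoint (CTSS/CTSB/GPI/GPE analog)."""

    block: str
    effect: float  # in units of noise_sd
    sign: int = 1


@dataclass(frozen=True)
class PlantedLate:
    """Genotype effect active only at the listed timepoints (NFL analog)."""

    block: str
    effect: float
    timepoints: tuple[str, ...] = ("36mo",)


@dataclass(frozen=True)
class PlantedAge:
    """Analyte drifting linearly with age in both genotypes."""

    block: str
    slope: float  # noise_sd units per month


def _default_planted_stable():
    return (
        PlantedStable("proteins", 3.0),
        PlantedStable("proteins", 3.0),
        PlantedStable("metabolites", 3.0),
        PlantedStable("metabolites", 3.0),
    )


def _default_planted_late():
    return (PlantedLate("proteins", 3.0), PlantedLate("metabolites", 3.0))


def _default_planted_age():
    return (PlantedAge("proteins", 0.02), PlantedAge("metabolites", 0.02))


@dataclass
class SimConfig:
    """Parameters of the synthetic longitudinal multi-omics cohort.

    Defaults reproduce the study design at desk scale: 6/9/9 samples per
    genotype at 6/24/36 months, longitudinal subjects, 40 proteins and 30
    metabolites with two stable 3 SD disease markers per block, one
    late-onset marker and one age-correlated analyte per block, three
    mixtures with additive batch shifts, and 5% MCAR missingness.
    """

    n_per_group: tuple[int, ...] = (6, 9, 9)
    timepoints: tuple[tuple[str, float], ...] = (("6mo", 6.0), ("24mo", 24.0), ("36mo", 36.0))
    n_proteins: int = 40
    n_metabolites: int = 30
    planted_stable: tuple[PlantedStable, ...] = field(default_factory=_default_planted_stable)
    planted_late: tuple[PlantedLate, ...] = field(default_factory=_default_planted_late)
    planted_age: tuple[PlantedAge, ...] = field(default_factory=_default_planted_age)
    subject_sd: float = 0.5
    noise_sd: float = 1.0
    n_mixtures: int = 3
    mixture_shift_sd: float = 0.3
    missing_rate: float = 0.05
    longitudinal: bool = True
    seed: int = 0

    def block_sizes(self) -> dict[str, int]:
        return {"proteins": self.n_proteins, "metabolites": self.n_metabolites}

    def validate(self) -> None:
        if len(self.n_per_group) != len(self.timepoints):
            raise ValueError("n_per_group must have one entry per timepoint")
        ages = [a for _, a in self.timepoints]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("timepoint ages must be strictly increasing")
        for name, v in [("subject_sd", self.subject_sd), ("noise_sd", self.noise_sd),
                        ("mixture_shift_sd", self.mixture_shift_sd)]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_mixtures < 1:
            raise ValueError("n_mixtures must be >= 1")
        sizes = self.block_sizes()
        planted = list(self.planted_stable) + list(self.planted_late) + list(self.planted_age)
        counts: dict[str, int] = {}
        for p in planted:
            if p.block not in sizes:
                raise ValueError(f"planted analyte names unknown block {p.block!r}")
            counts[p.block] = counts.get(p.block, 0) + 1
        for block, c in counts.items():
            if c > sizes[block]:
                raise ValueError(f"more planted analytes ({c}) than block size for {block!r}")
        known = {tp for tp, _ in self.timepoints}
        for p in self.planted_late:
            if not set(p.timepoints) <= known:
                raise ValueError(f"late effect names unknown timepoints {p.timepoints}")


@dataclass
class GroundTruth:
    """Everything planted by :func:`simulate_dataset`.

    ``stable``, ``late`` and ``age`` map analyte ids to their planted effect
    descriptions; ``mixture_shifts`` holds the per-analyte additive batch
    shifts and ``subject_intercepts`` the per-subject random intercepts.
    """

    stable: dict[str, PlantedStable]
    late: dict[str, PlantedLate]
    age: dict[str, PlantedAge]
    mixture_shifts: dict[str, pd.DataFrame]
    subject_intercepts: dict[str, pd.DataFrame]  # block -> subject x analyte

    def informative(self, block: str) -> list[str]:
        """Ids of analytes carrying a genotype effect (stable or late) in a block."""
        out = [aid for aid, p in self.stable.items() if p.block == block]
        out += [aid for aid, p in self.late.items() if p.block == block]
        return out

    def stable_ids(self, block: str) -> list[str]:
        return [aid for aid, p in self.stable.items() if p.block == block]


def _analyte_ids(block: str, n: int) -> list[str]:
    prefix = {"proteins": "PROT", "metabolites": "MET"}.get(block, block.upper())
    return [f"{prefix}{i:04d}" for i in range(n)]


def simulate_dataset(config: SimConfig) -> tuple[MultiOmicsDataset, GroundTruth]:
    """Simulate a longitudinal two-genotype multi-omics dataset.

    Each log2 abundance is built additively: analyte baseline + subject
    random intercept + genotype effect (if the analyte is planted and the
    timepoint active) + age slope x age + per-mixture batch shift + residual
    Normal(0, ``noise_sd``) noise. Entries are then masked missing
    independently with probability ``missing_rate``.

    Returns
    -------
    (MultiOmicsDataset, GroundTruth)
        The dataset and the record of all planted structure. Deterministic
        under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genotypes = ("WT", "MUT")
    tp_labels = [tp for tp, _ in config.timepoints]
    ages = dict(config.timepoints)
    max_n = max(config.n_per_group)

    # subjects: a per-genotype pool; longitudinal designs re-sample the first
    # n_t subjects at each timepoint, cross-sectional designs draw fresh ones
    rows = []
    if config.longitudinal:
        subject_pool = {g: [f"{g}{i+1:02d}" for i in range(max_n)] for g in genotypes}
        for tp, n_tp in zip(tp_labels, config.n_per_group):
            for g in genotypes:
                for subj in subject_pool[g][:n_tp]:
                    rows.append((f"{subj}_{tp}", subj, g, tp))
    else:
        counter = {g: 0 for g in genotypes}
        for tp, n_tp in zip(tp_labels, config.n_per_group):
            for g in genotypes:
                for _ in range(n_tp):
                    counter[g] += 1
                    subj = f"{g}{counter[g]:02d}"
                    rows.append((f"{subj}_{tp}", subj, g, tp))
    samples = pd.DataFrame(rows, columns=["sample_id", "subject_id", "genotype", "timepoint"])
    samples["age_months"] = samples["timepoint"].map(ages)
    subjects = sorted(samples["subject_id"].unique())
    sexes = {s: ("F" if rng.random() < 0.5 else "M") for s in subjects}
    samples["sex"] = samples["subject_id"].map(sexes)
    # balanced mixture assignment across genotype x timepoint strata
    mix = np.zeros(len(samples), dtype=int)
    for _, idx in samples.groupby(["timepoint", "genotype"]).indices.items():
        order = np.sort(idx)
        mix[order] = (np.arange(len(order)) % config.n_mixtures)
    samples["mixture"] = [f"mix{m+1}" for m in mix]
    samples = samples.set_index("sample_id")

    # assign planted analytes to the leading indices of each block
    sizes = config.block_sizes()
    ids = {b: _analyte_ids(b, n) for b, n in sizes.items()}
    cursor = {b: 0 for b in sizes}

    def take(block: str) -> str:
        aid = ids[block][cursor[block]]
        cursor[block] += 1
        return aid

    stable = {take(p.block): p for p in config.planted_stable}
    late = {take(p.block): p for p in config.planted_late}
    age_planted = {take(p.block): p for p in config.planted_age}

    blocks: dict[str, pd.DataFrame] = {}
    shifts: dict[str, pd.DataFrame] = {}
    annotations: dict[str, pd.DataFrame] = {}
    is_mut = (samples["genotype"] == "MUT").to_numpy()
    age_vec = samples["age_months"].to_numpy(dtype=float)
    subj_idx = samples["subject_id"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    mix_idx = mix
    intercepts: dict[str, pd.DataFrame] = {}

    for block, n_analytes in sizes.items():
        baseline = rng.normal(10.0, 1.0, size=n_analytes)
        shift = rng.normal(0.0, config.mixture_shift_sd, size=(config.n_mixtures, n_analytes))
        # random intercept per (subject, analyte): each analyte is correlated
        # within a subject across timepoints, without inducing a shared
        # factor (and hence analyte-analyte correlation) across the block
        subj_int = rng.normal(0.0, config.subject_sd, size=(len(subjects), n_analytes))
        intercepts[block] = pd.DataFrame(subj_int, index=subjects, columns=ids[block])
        X = (
            baseline[None, :]
            + subj_int[subj_idx, :]
            + shift[mix_idx, :]
            + rng.normal(0.0, config.noise_sd, size=(len(samples), n_analytes))
        )
        col_of = {aid: j for j, aid in enumerate(ids[block])}
        for aid, p in stable.items():
            if p.block == block:
                X[is_mut, col_of[aid]] += p.sign * p.effect * config.noise_sd
        for aid, p in late.items():
            if p.block == block:
                active = samples["timepoint"].isin(p.timepoints).to_numpy()
                X[is_mut & active, col_of[aid]] += p.effect * config.noise_sd
        for aid, p in age_planted.items():
            if p.block == block:
                X[:, col_of[aid]] += p.slope * config.noise_sd * age_vec
        if config.missing_rate > 0:
            mask = rng.random(X.shape) < config.missing_rate
            X = np.where(mask, np.nan, X)
        blocks[block] = pd.DataFrame(X, index=samples.index, columns=ids[block])
        shifts[block] = pd.DataFrame(
            shift, index=[f"mix{m+1}" for m in range(config.n_mixtures)], columns=ids[block]
        )
        annotations[block] = _annotate(block, ids[block], stable, rng)

    dataset = MultiOmicsDataset(blocks=blocks, samples=samples, annotations=annotations)
    truth = GroundTruth(
        stable=stable,
        late=late,
        age=age_planted,
        mixture_shifts=shifts,
        subject_intercepts=intercepts,
    )
    return dataset, truth


def _annotate(block, analyte_ids, stable, rng) -> pd.DataFrame:
    """One term per analyte; stable markers share the block's disease term."""
    vocab = PROTEIN_TERMS if block == "proteins" else METABOLITE_TERMS
    rows = []
    for aid in analyte_ids:
        if aid in stable and stable[aid].block == block:
            term = vocab[0]
        else:
            term = vocab[int(rng.integers(1, len(vocab)))]
        rows.append((aid, term))
    return pd.DataFrame(rows, columns=["analyte_id", "term"])


# --------------------------------------------------------------------------
# discrete DAG simulation for the network stage


def simulate_discrete_dag(
    n_samples: int,
    edges: list[tuple[str, str]],
    cpt_strength: float = 0.9,
    n_states: int = 2,
    seed: int = 0,
    nodes: list[str] | None = None,
) -> tuple[pd.DataFrame, Dag]:
    """Forward-sample a discrete dataset from a known DAG.

    Root nodes are uniform over ``n_states`` states. A child copies the sum
    of its parents' states (mod ``n_states``) with probability
    ``cpt_strength`` and is uniform otherwise, so ``cpt_strength`` directly
    controls parent-child association. With a single parent and strength
    ``s``, P(child = parent) = s + (1-s)/n_states.

    Returns the sample matrix (rows = samples, columns = nodes in topological
    order of the generating graph) and the generating :class:`Dag`.
    """
    if not 0 < cpt_strength < 1:
        raise ValueError("cpt_strength must be in (0, 1)")
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    node_set = set(itertools.chain.from_iterable(edges))
    if nodes is None:
        nodes = sorted(node_set) if node_set else []
    else:
        if not node_set <= set(nodes):
            raise ValueError("edges mention nodes absent from the node list")
    dag = Dag(nodes=list(nodes), edges=[(a, b, 1.0) for a, b in edges])  # validates acyclicity
    order = dag.topological_order()
    rng = np.random.default_rng(seed)
    data = {}
    for node in order:
        parents = dag.parents(node)
        if not parents:
            data[node] = rng.integers(0, n_states, size=n_samples)
        else:
            determ = np.sum([data[p] for p in parents], axis=0) % n_states
            noise = rng.integers(0, n_states, size=n_samples)
            copy = rng.random(n_samples) < cpt_strength
            data[node] = np.where(copy, determ, noise)
    return pd.DataFrame(data, columns=order).astype(int), dag
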