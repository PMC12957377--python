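"""End-to-end orchestration: simulate/load -> preprocess -> univariate ->
cluster -> sPLS-DA disease score -> Bayesian network.

Every intermediate is persisted as TSV/JSON under the output directory and
a manifest records the configuration, derived per-stage seeds and headline
results, so rerunning with the same config reproduces all outputs
bit-identically. A single global seed fans out to per-stage seeds by fixed
offsets, which keeps stages reproducible when rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cluster as cluster_mod
from . import network as network_mod
from . import preprocess as pp
from . import splsda as spl
from . import univariate as uni
from .datasets import MultiOmicsDataset, write_json
from .simulate import SimConfig, simulate_dataset

log = logging.getLogger(__name__)

SEED_OFFSETS = {"simulate": 0, "split": 1009, "tune": 2003, "network": 3001}


@dataclass
class PipelineConfig:
    """Parameters of a full pipeline run; see each stage module for details."""

    outdir: str = "longomics_out"
    seed: int = 0
    data_dir: str | None = None  # load this dataset instead of simulating
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    alpha: float = 0.05
    enrichment_min: float = 3.0
    fdr_max: float = 0.1
    cluster_k: int | None = None  # None -> elbow
    k_range: tuple[int, int] = (2, 8)
    train_frac: float = 0.7
    n_components: int = 2
    keepx: dict = field(
        default_factory=lambda: {"proteins": (2, 1), "metabolites": (2, 1)}
    )
    tune: bool = False
    tune_grid_max: int = 3
    folds: int = 5
    repeats: int = 2
    network_timepoint: str | None = None  # None -> last timepoint
    n_intervals: int = 20
    discretize_mode: str = "equal_width"
    max_parents: int = 3
    ess: float = 1.0
    edge_threshold: float = 0.001

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown pipeline config keys: {sorted(bad)}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return (self.seed + SEED_OFFSETS[stage]) % (2**31 - 1)

    def validate(self) -> None:
        if self.data_dir is not None and not Path(self.data_dir).is_dir():
            raise ValueError(f"data_dir does not exist: {self.data_dir}")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")


def preprocess_blocks(dataset: MultiOmicsDataset):
    """Bridge + filter each block (protein rule for proteins, metabolite
    rule otherwise); return unscaled filtered blocks and reports."""
    filtered, reports = {}, {}
    for name, X in dataset.blocks.items():
        rule = "nonstrict" if name == "proteins" else "strict"
        Xp, report = pp.preprocess_block(
            X, mixture_ids=dataset.samples["mixture"], already_log2=True,
            missing_rule=rule, scale=False,
        )
        filtered[name] = Xp
        reports[name] = report
    return filtered, reports


def disease_score_stage(
    filtered: dict[str, pd.DataFrame],
    samples: pd.DataFrame,
    config: PipelineConfig,
) -> dict:
    """Grouped split, optional keepX tuning, fit, and held-out evaluation.

    Scaling and imputation parameters are estimated on the training split
    only and applied to the held-out samples.
    """
    dataset = MultiOmicsDataset(blocks=filtered, samples=samples)
    train, test = spl.grouped_split(dataset, config.train_frac, config.stage_seed("split"))
    tr_blocks, te_blocks = {}, {}
    for b in filtered:
        scaled, params = pp.scale_unit_variance(train.blocks[b])
        imputed, medians = pp.median_impute(scaled)
        tr_blocks[b] = imputed
        te = pp.apply_scaling(test.blocks[b], params)
        te_blocks[b], _ = pp.median_impute(te, medians)
    outcome = spl.OutcomeBlock.from_labels(train.samples["genotype"].to_numpy())
    cv = None
    keepx = {b: tuple(v) for b, v in config.keepx.items()}
    if config.tune:
        grid = []
        for kp in range(1, config.tune_grid_max + 1):
            for km in range(1, config.tune_grid_max + 1):
                grid.append({"proteins": (kp,), "metabolites": (km,)})
        cv = spl.tune_keepx(
            tr_blocks, outcome, grid, train.samples["subject_id"].to_numpy(),
            folds=config.folds, repeats=config.repeats, seed=config.stage_seed("tune"),
        )
        chosen = cv.chosen_keepx
        keepx = {
            b: tuple(chosen.get(b, (1,))) + (1,) * (config.n_components - len(chosen.get(b, (1,))))
            for b in filtered
        }
    model = spl.fit(tr_blocks, outcome, spl.SplsdaConfig(config.n_components, keepx))
    te_scores = spl.transform(model, te_blocks)
    score_te = spl.spls_score(model, te_scores)
    score_tr = spl.spls_score(model, {b: model.scores[b] for b in model.block_names})
    auc, curve = spl.roc_auc(score_te, test.samples["genotype"].to_numpy(), positive="MUT")
    pred = spl.classify(model, te_scores)
    ber = spl.balanced_error_rate(test.samples["genotype"].to_numpy(), pred)
    score_table = pd.concat([
        pd.DataFrame({"sample_id": train.samples.index, "split": "train",
                      "genotype": train.samples["genotype"].to_numpy(),
                      "spls_score": score_tr}),
        pd.DataFrame({"sample_id": test.samples.index, "split": "test",
                      "genotype": test.samples["genotype"].to_numpy(),
                      "spls_score": score_te}),
    ], ignore_index=True)
    return {
        "model": model, "cv": cv, "keepx": keepx, "scores": score_table,
        "test_auc": float(auc), "roc_curve": curve, "test_ber": float(ber),
        "selected": model.selected_analytes(0),
        "train_subjects": sorted(train.samples["subject_id"].unique()),
        "test_subjects": sorted(test.samples["subject_id"].unique()),
    }


def network_stage(
    filtered: dict[str, pd.DataFrame],
    samples: pd.DataFrame,
    differential: pd.DataFrame,
    config: PipelineConfig,
) -> dict:
    """Per-animal fold changes of timepoint-significant analytes -> DAG."""
    tp = config.network_timepoint or samples["timepoint"].iloc[-1]
    sig = differential[(differential["timepoint"] == tp) & differential["associated"]]
    fcs = []
    for b, X in filtered.items():
        keep = [a for a in sig[sig["block"] == b]["analyte_id"] if a in X.columns]
        if keep:
            fcs.append(uni.log2fc_vs_wt_mean(X[keep], samples, tp))
    if not fcs:
        log.warning("no genotype-associated analytes at %s; empty network", tp)
        return {"dag": network_mod.Dag(nodes=[]), "subnetwork": network_mod.Dag(nodes=[]),
                "timepoint": tp, "n_variables": 0}
    fc = pd.concat(fcs, axis=1)
    fc, _ = pp.median_impute(fc)
    disc = network_mod.discretize(fc, config.discretize_mode, config.n_intervals)
    dag = network_mod.hill_climb(
        disc, max_parents=config.max_parents, ess=config.ess,
        seed=config.stage_seed("network"),
    )
    sub = network_mod.extract_subnetwork(dag, config.edge_threshold)
    return {"dag": dag, "subnetwork": sub, "timepoint": tp, "n_variables": fc.shape[1]}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order, persisting all intermediates.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    if config.data_dir:
        dataset = MultiOmicsDataset.from_dir(config.data_dir)
        truth = None
    else:
        sim_cfg = SimConfig(**{**config.sim, "seed": config.stage_seed("simulate")})
        dataset, truth = simulate_dataset(sim_cfg)
    dataset.to_dir(out / "data")
    if truth is not None:
        write_json(
            {
                "stable": {a: dataclasses.asdict(p) for a, p in truth.stable.items()},
                "late": {a: dataclasses.asdict(p) for a, p in truth.late.items()},
                "age": {a: dataclasses.asdict(p) for a, p in truth.age.items()},
            },
            out / "data" / "ground_truth.json",
        )

    filtered, reports = preprocess_blocks(dataset)
    write_json({b: r.to_dict() for b, r in reports.items()}, out / "preprocess_report.json")
    scaled = {b: pp.scale_unit_variance(X)[0] for b, X in filtered.items()}
    for b, X in scaled.items():
        X.to_csv(out / f"processed_{b}.tsv", sep="\t", index_label="sample_id", na_rep="")

    differential = uni.differential_all_timepoints(
        MultiOmicsDataset(blocks=scaled, samples=dataset.samples,
                          annotations=dataset.annotations),
        alpha=config.alpha,
    )
    differential.to_csv(out / "differential.tsv", sep="\t", index=False)
    enrich_tables = []
    for (b, tp), sub in differential.groupby(["block", "timepoint"]):
        ann = dataset.annotations.get(b)
        if ann is None:
            continue
        fg = sub[sub["associated"]]["analyte_id"]
        if len(fg) == 0:
            continue
        res = uni.fisher_enrichment(fg, ann, sub[sub["tested"]]["analyte_id"])
        res.insert(0, "timepoint", tp)
        res.insert(0, "block", b)
        enrich_tables.append(res)
    enrichment = pd.concat(enrich_tables, ignore_index=True) if enrich_tables else pd.DataFrame()
    enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    scaled_ds = MultiOmicsDataset(blocks=scaled, samples=dataset.samples)
    embedding = cluster_mod.pca_embedding(scaled_ds)
    embedding.to_csv(out / "embedding.tsv", sep="\t", index_label="analyte_id")
    k = config.cluster_k or cluster_mod.choose_k_elbow(
        embedding, range(config.k_range[0], config.k_range[1] + 1)
    )
    assignments = cluster_mod.hierarchical_cluster(embedding, k)
    assignments.to_csv(out / "clusters.tsv", sep="\t", index=False)
    ann_all = (
        pd.concat(dataset.annotations.values(), ignore_index=True)
        if dataset.annotations else pd.DataFrame(columns=["analyte_id", "term"])
    )
    if len(ann_all):
        cluster_enr = cluster_mod.cluster_term_enrichment(
            assignments, ann_all, config.enrichment_min, config.fdr_max
        )
        cluster_enr.to_csv(out / "cluster_enrichment.tsv", sep="\t", index=False)

    score = disease_score_stage(filtered, dataset.samples, config)
    score["scores"].to_csv(out / "spls_scores.tsv", sep="\t", index=False)
    score["roc_curve"].to_csv(out / "roc_curve.tsv", sep="\t", index=False)
    if score["cv"] is not None:
        score["cv"].to_frame().to_csv(out / "cv_ber.tsv", sep="\t", index=False)
    write_json(score["model"].to_dict(), out / "splsda_model.json")

    net = network_stage(filtered, dataset.samples, differential, config)
    net["dag"].to_sif(out / "network.sif")
    net["subnetwork"].to_sif(out / "subnetwork.sif")
    net["dag"].to_graphml(out / "network.graphml")
    edge_rows = [
        {"source": u, "target": v, "weight": w,
         "raw_delta": net["dag"].edge_deltas.get((u, v))}
        for u, v, w in net["dag"].edges
    ]
    pd.DataFrame(edge_rows, columns=["source", "target", "weight", "raw_delta"]).to_csv(
        out / "network_edges.tsv", sep="\t", index=False
    )

    from . import __version__

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stage_seeds": {s: config.stage_seed(s) for s in SEED_OFFSETS},
        "n_samples": dataset.n_samples,
        "blocks": {b: X.shape[1] for b, X in filtered.items()},
        "cluster_k": int(k),
        "keepx": {b: list(v) for b, v in score["keepx"].items()},
        "selected_analytes": score["selected"],
        "test_auc": score["test_auc"],
        "test_ber": score["test_ber"],
        "network": {
            "timepoint": str(net["timepoint"]),
            "n_variables": net["n_variables"],
            "n_edges": len(net["dag"].edges),
            "n_subnetwork_edges": len(net["subnetwork"].edges),
            "bde_score": net["dag"].score,
        },
        "outputs": sorted(
            p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        ),
    }
    write_json(manifest, out / "manifest.json")
    return manifest
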