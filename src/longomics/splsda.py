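"""Multiblock sparse PLS-DA with a composite continuous disease score.

Given centered-and-scaled omics blocks :math:`X^{(q)}` (samples x analytes)
and a class-indicator outcome :math:`Y` (samples x groups), each component
:math:`h` finds unit-norm loading vectors :math:`a_h^{(q)}` maximizing the
design-weighted sum of covariances

.. math::

    \\sum_{q<k} C_{q,k}\\,\\mathrm{cov}\\big(X_h^{(q)} a_h^{(q)},\\;
    X_h^{(k)} a_h^{(k)}\\big)

where the centered outcome is treated as one of the blocks, subject to
:math:`\\|a_h^{(q)}\\|_2 = 1` and at most ``keepX`` nonzero entries per
omics block. The maximization alternates exact block updates: with all
other block scores fixed, the optimal loading under the cardinality
constraint is the gradient :math:`w = X^{(q)\\top}\\sum_k C_{q,k} t^{(k)}`
restricted to its ``keepX`` largest-magnitude entries and renormalized, so
the objective is non-decreasing across iterations. After each component
every block (and the outcome) is deflated by regression on its own score.

The composite sPLS disease score of a sample is the sum of its
first-component scores over the omics blocks,
:math:`t_1^{(M)} + t_1^{(P)}` — a single continuous index combining the
selected metabolite and protein markers. Model selection (how many analytes
each component may keep) minimizes the balanced error rate of the induced
classifier under repeated subject-grouped cross-validation.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Y_BLOCK = "_outcome"


# ----------------------------------------------------------------- outcome


@dataclass
class OutcomeBlock:
    """Class-indicator outcome matrix with its centering parameters."""

    Y: np.ndarray  # N x G, one-hot
    classes: list[str]
    labels: np.ndarray  # N, class names

    @classmethod
    def from_labels(cls, labels) -> "OutcomeBlock":
        labels = np.asarray(labels)
        classes = sorted(pd.unique(labels))
        if len(classes) < 2:
            raise ValueError("outcome needs at least two classes")
        Y = np.stack([(labels == c).astype(float) for c in classes], axis=1)
        return cls(Y=Y, classes=classes, labels=labels)

    @property
    def col_means(self) -> np.ndarray:
        return self.Y.mean(axis=0)

    def centered(self) -> np.ndarray:
        return self.Y - self.col_means


# ------------------------------------------------------------------ config


@dataclass
class SplsdaConfig:
    """Hyperparameters of a multiblock sPLS-DA fit.

    ``keepx`` maps block name -> per-component nonzero counts; ``None``
    means the full block width (classical PLS-DA limit). ``design`` is the
    symmetric block-pair weight matrix C, given as a scalar applied to every
    pair (default 1: fully connected) or a dict keyed by frozenset pairs of
    block names (use :data:`Y_BLOCK` for the outcome).
    """

    n_components: int = 2
    keepx: dict[str, tuple[int, ...]] | None = None
    design: float | dict = 1.0
    tol: float = 1e-6
    max_iter: int = 500
    exclude_analytes: tuple[str, ...] = ()

    def design_weight(self, a: str, b: str) -> float:
        if isinstance(self.design, dict):
            w = float(self.design.get(frozenset((a, b)), 0.0))
        else:
            w = float(self.design)
        if not 0 <= w <= 1:
            raise ValueError("design weights must lie in [0, 1]")
        return w

    def keepx_for(self, block: str, width: int) -> tuple[int, ...]:
        if self.keepx is None or block not in self.keepx:
            return tuple([width] * self.n_components)
        kx = self.keepx[block]
        if isinstance(kx, int):
            kx = (kx,) + (1,) * (self.n_components - 1)
        kx = tuple(int(k) for k in kx)
        if len(kx) != self.n_components:
            raise ValueError(
                f"keepx for {block!r} has {len(kx)} entries for {self.n_components} components"
            )
        if any(k < 1 or k > width for k in kx):
            raise ValueError(f"keepx for {block!r} outside [1, {width}]: {kx}")
        return kx


# ------------------------------------------------------------------- model


@dataclass
class SplsdaModel:
    """Fitted loadings, scores, centroids and deflation state."""

    block_names: list[str]
    analytes: dict[str, list[str]]
    loadings: dict[str, list[pd.Series]]  # block -> per-component loading
    y_loadings: list[np.ndarray]
    defl_coefs: dict[str, list[pd.Series]]  # regression deflation vectors
    scores: dict[str, np.ndarray]  # training scores, N x H
    y_scores: np.ndarray
    centroids: dict[str, pd.DataFrame]  # class x component
    block_means: dict[str, pd.Series]
    block_sds: dict[str, pd.Series] | None
    dummy_coefs: dict[str, np.ndarray]  # score -> class-indicator regression
    outcome: OutcomeBlock
    config: SplsdaConfig
    objective_history: list[list[float]] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.y_loadings)

    def selected_analytes(self, component: int = 0) -> dict[str, list[str]]:
        """Analytes with nonzero loading on one component, per block."""
        return {
            b: list(self.loadings[b][component].index[self.loadings[b][component] != 0])
            for b in self.block_names
        }

    def to_dict(self) -> dict:
        return {
            "block_names": self.block_names,
            "classes": self.outcome.classes,
            "n_components": self.n_components,
            "loadings": {
                b: [ld.to_dict() for ld in lds] for b, lds in self.loadings.items()
            },
            "y_loadings": [v.tolist() for v in self.y_loadings],
            "defl_coefs": {
                b: [c.to_dict() for c in cs] for b, cs in self.defl_coefs.items()
            },
            "centroids": {b: c.to_dict() for b, c in self.centroids.items()},
            "block_means": {b: m.to_dict() for b, m in self.block_means.items()},
            "block_sds": (
                None if self.block_sds is None
                else {b: s.to_dict() for b, s in self.block_sds.items()}
            ),
            "keepx": self.config.keepx,
        }


def _sparsify(w: np.ndarray, keep: int) -> np.ndarray:
    """Exact maximizer of w.a under unit L2 norm and cardinality <= keep."""
    if keep < w.size:
        order = np.argsort(-np.abs(w), kind="stable")
        out = np.zeros_like(w)
        out[order[:keep]] = w[order[:keep]]
        w = out
    nrm = np.linalg.norm(w)
    return w / nrm if nrm > 0 else w


def _objective(ts: dict[str, np.ndarray], config: SplsdaConfig, n: int) -> float:
    names = list(ts)
    total = 0.0
    for a, b in itertools.combinations(names, 2):
        total += config.design_weight(a, b) * float(ts[a] @ ts[b]) / (n - 1)
    return total


def _component_starts(Xh, Yh, names, max_joint: int = 64):
    """Deterministic initializations for one component's alternating solve.

    The first start takes each block's loading from the dominant left
    singular vector of X^T Yc. The sparse fixed-point iteration can stall in
    support-local optima on weak-signal data, so when the blocks are narrow
    enough (product of widths <= ``max_joint``) every joint combination of
    single-analyte basis vectors is added as an extra start and the best
    converged objective wins; on wide blocks the SVD start is used alone.
    """
    svd_init = {}
    for b in names:
        M = Xh[b].T @ Yh
        if np.allclose(M, 0):
            v = np.zeros(Xh[b].shape[1])
            v[0] = 1.0
        else:
            v = np.linalg.svd(M, full_matrices=False)[0][:, 0]
        svd_init[b] = v
    starts = [svd_init]
    widths = [Xh[b].shape[1] for b in names]
    if int(np.prod(widths)) <= max_joint:
        for combo in itertools.product(*[range(w) for w in widths]):
            start = {}
            for b, i in zip(names, combo):
                v = np.zeros(Xh[b].shape[1])
                v[i] = 1.0
                start[b] = v
            starts.append(start)
    return starts


def _solve_component(Xh, Yh, names, keepx_h, config, n):
    """Alternating exact sparse maximization of one component.

    Runs the fixed-point iteration from every deterministic start and keeps
    the solution with the highest final objective. Within a start the
    objective is non-decreasing, since each block update is the exact
    maximizer given the other blocks' scores.
    """
    best = None
    for init in _component_starts(Xh, Yh, names):
        a = {b: init[b].copy() for b in names}
        t = {b: Xh[b] @ a[b] for b in names}
        wy = Yh.T @ sum(config.design_weight(Y_BLOCK, b) * t[b] for b in names)
        ay = _sparsify(wy, wy.size)
        t[Y_BLOCK] = Yh @ ay
        traj = []
        converged = False
        for _ in range(config.max_iter):
            prev = np.concatenate([a[b] for b in names] + [ay])
            for b in names:
                grad = np.zeros(n)
                for k in names:
                    if k != b:
                        grad += config.design_weight(b, k) * t[k]
                grad += config.design_weight(b, Y_BLOCK) * t[Y_BLOCK]
                w = Xh[b].T @ grad
                if not np.allclose(w, 0):
                    a[b] = _sparsify(w, keepx_h[b])
                t[b] = Xh[b] @ a[b]
            wy = Yh.T @ sum(config.design_weight(Y_BLOCK, b) * t[b] for b in names)
            if not np.allclose(wy, 0):
                ay = _sparsify(wy, wy.size)
            t[Y_BLOCK] = Yh @ ay
            traj.append(_objective(t, config, n))
            cur = np.concatenate([a[b] for b in names] + [ay])
            if np.max(np.abs(cur - prev)) < config.tol:
                converged = True
                break
        if best is None or traj[-1] > best[3][-1] + 1e-12:
            best = (a, ay, t, traj, converged)
    return best


def fit(
    blocks: dict[str, pd.DataFrame],
    outcome: OutcomeBlock,
    config: SplsdaConfig | None = None,
    center: bool = True,
    scale: bool = False,
) -> SplsdaModel:
    """Fit a multiblock sPLS-DA model.

    ``blocks`` must be complete (impute missing values upstream) and share
    the sample order of ``outcome``. Blocks are centered (and optionally
    unit-variance scaled) internally with the parameters stored for
    held-out projection. Loadings are initialized from the dominant left
    singular vector of :math:`X^{(q)\\top} Y_c`, updated by alternating
    exact sparse maximization until the largest loading change drops below
    ``config.tol``, and sign-anchored per component by a single global flip
    so the first block's largest-magnitude loading entry is positive.
    """
    config = config or SplsdaConfig()
    names = list(blocks)
    if not names:
        raise ValueError("at least one block is required")
    n = len(outcome.labels)
    X0, means, sds, analytes = {}, {}, {}, {}
    for b, df in blocks.items():
        if config.exclude_analytes:
            df = df.drop(columns=[c for c in config.exclude_analytes if c in df.columns])
        if df.isna().any().any():
            raise ValueError(f"block {b!r} contains missing values; impute upstream")
        if len(df) != n:
            raise ValueError(f"block {b!r} has {len(df)} rows for {n} outcome labels")
        analytes[b] = list(df.columns)
        X = df.to_numpy(dtype=float)
        mu = X.mean(axis=0)
        means[b] = pd.Series(mu, index=df.columns)
        X = X - mu
        if scale:
            sd = X.std(axis=0, ddof=1)
            if np.any(sd <= 0):
                raise ValueError(f"zero-variance analytes in block {b!r}")
            sds[b] = pd.Series(sd, index=df.columns)
            X = X / sd
        X0[b] = X
    Yc = outcome.centered()
    keepx = {b: config.keepx_for(b, X0[b].shape[1]) for b in names}

    loadings: dict[str, list[pd.Series]] = {b: [] for b in names}
    y_loadings: list[np.ndarray] = []
    defl: dict[str, list[pd.Series]] = {b: [] for b in names}
    scores: dict[str, list[np.ndarray]] = {b: [] for b in names}
    y_scores: list[np.ndarray] = []
    history: list[list[float]] = []

    Xh = {b: X0[b].copy() for b in names}
    Yh = Yc.copy()
    for h in range(config.n_components):
        a, ay, t, traj, converged = _solve_component(
            Xh, Yh, names, {b: keepx[b][h] for b in names}, config, n
        )
        if not converged:
            warnings.warn(
                f"component {h + 1}: no convergence in {config.max_iter} iterations; "
                "using the final iterate",
                stacklevel=2,
            )
        history.append(traj)
        # one global sign flip per component, anchored on the first block
        anchor = a[names[0]]
        if anchor[np.argmax(np.abs(anchor))] < 0:
            for b in names:
                a[b] = -a[b]
                t[b] = -t[b]
            ay = -ay
            t[Y_BLOCK] = -t[Y_BLOCK]
        for b in names:
            loadings[b].append(pd.Series(a[b], index=analytes[b]))
            scores[b].append(t[b])
            denom = float(t[b] @ t[b])
            c = Xh[b].T @ t[b] / denom if denom > 0 else np.zeros(Xh[b].shape[1])
            defl[b].append(pd.Series(c, index=analytes[b]))
            Xh[b] = Xh[b] - np.outer(t[b], c)
        y_loadings.append(ay)
        y_scores.append(t[Y_BLOCK])
        dy = float(t[Y_BLOCK] @ t[Y_BLOCK])
        if dy > 0:
            Yh = Yh - np.outer(t[Y_BLOCK], Yh.T @ t[Y_BLOCK] / dy)

    score_mats = {b: np.column_stack(scores[b]) for b in names}
    centroids = {}
    dummy = {}
    for b in names:
        T = score_mats[b]
        centroids[b] = pd.DataFrame(
            [T[outcome.labels == c].mean(axis=0) for c in outcome.classes],
            index=outcome.classes,
            columns=[f"comp{h + 1}" for h in range(config.n_components)],
        )
        dummy[b], *_ = np.linalg.lstsq(
            np.column_stack([T, np.ones(n)]), outcome.Y, rcond=None
        )
    return SplsdaModel(
        block_names=names,
        analytes=analytes,
        loadings=loadings,
        y_loadings=y_loadings,
        defl_coefs=defl,
        scores=score_mats,
        y_scores=np.column_stack(y_scores),
        centroids=centroids,
        block_means=means,
        block_sds=sds or None,
        dummy_coefs=dummy,
        outcome=outcome,
        config=config,
        objective_history=history,
    )


def transform(model: SplsdaModel, blocks: dict[str, pd.DataFrame]) -> dict[str, np.ndarray]:
    """Project new samples onto the fitted components, block by block.

    Applies the stored centering/scaling, then for each component computes
    the score with the training loading and deflates with the training
    regression vector, exactly reproducing the training scores on the
    training data.
    """
    out = {}
    for b in model.block_names:
        if b not in blocks:
            raise ValueError(f"block {b!r} missing from input")
        df = blocks[b]
        absent = [c for c in model.analytes[b] if c not in df.columns]
        if absent:
            raise ValueError(f"block {b!r} lacks training analytes: {absent}")
        X = df[model.analytes[b]].to_numpy(dtype=float)
        X = X - model.block_means[b].to_numpy()
        if model.block_sds is not None and b in model.block_sds:
            X = X / model.block_sds[b].to_numpy()
        ts = []
        for h in range(model.n_components):
            t = X @ model.loadings[b][h].to_numpy()
            ts.append(t)
            X = X - np.outer(t, model.defl_coefs[b][h].to_numpy())
        out[b] = np.column_stack(ts)
    return out


# ------------------------------------------------------------ classification


def _block_distances(model: SplsdaModel, scores: dict[str, np.ndarray], distance: str):
    """Per block, an (n_samples x n_classes) dissimilarity array."""
    dists = {}
    for b in model.block_names:
        T = scores[b]
        if distance == "centroid":
            cent = model.centroids[b].to_numpy()
            d = np.linalg.norm(T[:, None, :] - cent[None, :, :], axis=2)
        elif distance == "max":
            pred = np.column_stack([T, np.ones(len(T))]) @ model.dummy_coefs[b]
            d = -pred  # larger predicted indicator = closer
        else:
            raise ValueError(f"unknown distance {distance!r}")
        dists[b] = d
    return dists


def classify(
    model: SplsdaModel,
    scores: dict[str, np.ndarray],
    distance: str = "centroid",
    vote: str = "majority",
) -> np.ndarray:
    """Combine per-block nearest-class decisions into final labels.

    ``majority`` takes the modal per-block class (ties broken by the
    smallest aggregate distance over blocks, then by class order);
    ``weighted`` weights each block's vote by the absolute training
    correlation of its first component with the outcome; ``average``
    averages the per-block distance profiles and takes the nearest class.
    """
    if vote not in ("majority", "weighted", "average"):
        raise ValueError(f"unknown vote {vote!r}")
    classes = model.outcome.classes
    dists = _block_distances(model, scores, distance)
    n = next(iter(dists.values())).shape[0]
    agg = sum(dists.values())
    if vote == "average":
        return np.array([classes[i] for i in agg.argmin(axis=1)])
    if vote == "weighted":
        y_num = model.outcome.centered()[:, -1]
        weights = {
            b: abs(float(np.corrcoef(model.scores[b][:, 0], y_num)[0, 1]))
            for b in model.block_names
        }
    else:
        weights = {b: 1.0 for b in model.block_names}
    out = []
    for i in range(n):
        tally = {c: 0.0 for c in classes}
        for b in model.block_names:
            tally[classes[int(dists[b][i].argmin())]] += weights[b]
        top = max(tally.values())
        tied = [c for c in classes if tally[c] == top]
        if len(tied) == 1:
            out.append(tied[0])
        else:  # tie-break: smallest aggregate distance, then class order
            sub = [(agg[i][classes.index(c)], classes.index(c)) for c in tied]
            out.append(classes[min(sub)[1]])
    return np.array(out)


def balanced_error_rate(y_true, y_pred) -> float:
    """Mean over classes of each class's misclassification fraction."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have the same length")
    rates = []
    for c in pd.unique(y_true):
        mask = y_true == c
        if mask.sum() == 0:
            raise ValueError(f"empty class {c!r}")
        rates.append(float((y_pred[mask] != c).mean()))
    return float(np.mean(rates))


# --------------------------------------------------------------- splitting


def split_subjects(
    metadata: pd.DataFrame, train_frac: float = 0.7, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Partition subject ids into train/test, stratified by genotype.

    The overall train count is round(train_frac * n_subjects), apportioned
    to genotypes by largest remainder; every class keeps at least one
    subject on each side.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    per_class = (
        metadata.drop_duplicates("subject_id").groupby("genotype")["subject_id"].apply(list)
    )
    if (per_class.apply(len) < 2).any():
        raise ValueError("each genotype needs at least 2 subjects to stratify the split")
    rng = np.random.default_rng(seed)
    n_total = int(per_class.apply(len).sum())
    target_total = int(round(train_frac * n_total))
    raw = {c: train_frac * len(subj) for c, subj in per_class.items()}
    take = {c: int(np.floor(v)) for c, v in raw.items()}
    for c in per_class.index:
        take[c] = min(max(take[c], 1), len(per_class[c]) - 1)
    remainders = sorted(per_class.index, key=lambda c: (-(raw[c] - np.floor(raw[c])), c))
    i = 0
    while sum(take.values()) < target_total and i < 10 * len(per_class):
        c = remainders[i % len(remainders)]
        if take[c] < len(per_class[c]) - 1:
            take[c] += 1
        i += 1
    train, test = [], []
    for c in sorted(per_class.index):
        subj = sorted(per_class[c])
        perm = rng.permutation(len(subj))
        chosen = {subj[j] for j in perm[: take[c]]}
        train += sorted(chosen)
        test += sorted(set(subj) - chosen)
    return train, test


def grouped_split(dataset, train_frac: float = 0.7, seed: int = 0):
    """Split a dataset by subject id (all of a subject's samples together)."""
    train_subj, test_subj = split_subjects(dataset.samples, train_frac, seed)
    meta = dataset.samples
    train_ids = meta.index[meta["subject_id"].isin(train_subj)]
    test_ids = meta.index[meta["subject_id"].isin(test_subj)]
    return dataset.subset_samples(train_ids), dataset.subset_samples(test_ids)


# ------------------------------------------------------------------ tuning


@dataclass
class CvResult:
    """Balanced-error-rate surface over a keepX grid."""

    grid: list[dict[str, tuple[int, ...]]]
    mean_ber: np.ndarray
    sd_ber: np.ndarray
    chosen: int
    fold_assignments: list[dict[str, int]]  # per repeat: group -> fold
    argmin: int = 0  # cell with the lowest mean BER, before the parsimony rule

    @property
    def chosen_keepx(self) -> dict[str, tuple[int, ...]]:
        return self.grid[self.chosen]

    @property
    def chosen_ber(self) -> tuple[float, float]:
        return float(self.mean_ber[self.chosen]), float(self.sd_ber[self.chosen])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cell, m, s in zip(self.grid, self.mean_ber, self.sd_ber):
            rows.append({
                "keepx": ";".join(f"{b}={','.join(map(str, v))}" for b, v in cell.items()),
                "mean_ber": m,
                "sd_ber": s,
            })
        df = pd.DataFrame(rows)
        df["chosen"] = False
        df.loc[self.chosen, "chosen"] = True
        return df


def _grouped_folds(groups, labels, folds, rng):
    """Stratified partition of groups into folds (group -> fold index)."""
    by_class: dict = {}
    for g, c in zip(groups, labels):
        by_class.setdefault(c, set()).add(g)
    assign = {}
    for c in sorted(by_class):
        gs = sorted(by_class[c])
        perm = rng.permutation(len(gs))
        for pos, j in enumerate(perm):
            assign[gs[j]] = pos % folds
    return assign


def tune_keepx(
    blocks: dict[str, pd.DataFrame],
    outcome: OutcomeBlock,
    grid,
    group_ids,
    folds: int = 5,
    repeats: int = 20,
    seed: int = 0,
    distance: str = "centroid",
    vote: str = "majority",
) -> CvResult:
    """Choose keepX by repeated subject-grouped cross-validated BER.

    Folds partition groups (subjects), never samples, stratified by class so
    every fold sees both classes; a fold whose training split still lacks a
    class is skipped with a warning. The chosen cell follows the
    one-standard-error parsimony rule: among cells whose mean BER is within
    one standard error of the lowest mean, the one keeping the fewest
    analytes wins (ties by grid order). Arg-min selection on a fold-noisy
    BER surface tends to admit spuriously large cardinalities; the raw
    arg-min cell is still reported in ``CvResult.argmin``. Deterministic
    under ``seed``.
    """
    grid = [dict(cell) for cell in grid]
    if not grid:
        raise ValueError("empty keepX grid")
    group_ids = np.asarray(group_ids)
    n_groups = len(pd.unique(group_ids))
    if folds > n_groups:
        raise ValueError(f"{folds} folds for {n_groups} groups")
    ncomp = {len(tuple(v) if not isinstance(v, int) else (v,)) for cell in grid for v in cell.values()}
    n_components = max(ncomp)
    labels = outcome.labels
    group_class = pd.Series(labels, index=group_ids).groupby(level=0).first()
    bers = np.full((len(grid), repeats * folds), np.nan)
    assignments = []
    rng = np.random.default_rng(seed)
    for r in range(repeats):
        assign = _grouped_folds(group_class.index, group_class.values, folds, rng)
        assignments.append(assign)
        fold_of = np.array([assign[g] for g in group_ids])
        for f in range(folds):
            tr = fold_of != f
            te = ~tr
            if len(set(labels[tr])) < len(outcome.classes) or te.sum() == 0:
                log.warning("repeat %d fold %d lacks a class; skipped", r, f)
                continue
            sub_out = OutcomeBlock.from_labels(labels[tr])
            tr_blocks = {b: X.iloc[tr] for b, X in blocks.items()}
            te_blocks = {b: X.iloc[te] for b, X in blocks.items()}
            for ci, cell in enumerate(grid):
                cfg = SplsdaConfig(n_components=n_components, keepx=cell)
                model = fit(tr_blocks, sub_out, cfg)
                pred = classify(model, transform(model, te_blocks), distance, vote)
                bers[ci, r * folds + f] = balanced_error_rate(labels[te], pred)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(bers, axis=1)
        sd = np.nanstd(bers, axis=1, ddof=1)

    def total_kept(cell):
        return sum(sum(v) if not isinstance(v, int) else v for v in cell.values())

    order = sorted(range(len(grid)), key=lambda i: (mean[i], total_kept(grid[i]), i))
    argmin = order[0]
    n_eval = int(np.sum(~np.isnan(bers[argmin])))
    se = sd[argmin] / np.sqrt(n_eval) if n_eval > 1 else 0.0
    within = [i for i in range(len(grid)) if mean[i] <= mean[argmin] + se]
    chosen = min(within, key=lambda i: (total_kept(grid[i]), i))
    return CvResult(grid=grid, mean_ber=mean, sd_ber=sd, chosen=chosen,
                    fold_assignments=assignments, argmin=argmin)


# ------------------------------------------------------------------- score


def spls_score(model: SplsdaModel, scores: dict[str, np.ndarray]) -> np.ndarray:
    """Composite disease score: sum of first-component scores over blocks."""
    out = None
    for b in model.block_names:
        if b not in scores:
            raise ValueError(f"block {b!r} missing from the score dictionary")
        if scores[b].ndim != 2 or scores[b].shape[1] < 1:
            raise ValueError("scores need at least one component per block")
        out = scores[b][:, 0] if out is None else out + scores[b][:, 0]
    return out


def roc_auc(scores, labels, positive=None) -> tuple[float, pd.DataFrame]:
    """ROC AUC by the rank (Mann-Whitney) formulation, plus curve points.

    Ties contribute 1/2. The curve is a threshold sweep over the observed
    scores; its trapezoidal integral equals the rank AUC.
    """
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if positive is None:
        classes = sorted(pd.unique(labels))
        if len(classes) != 2:
            raise ValueError("labels must be binary (or pass positive=)")
        positive = classes[-1]
    pos = labels == positive
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(pos[order])
    fps = np.cumsum(~pos[order])
    # collapse tied thresholds to one point each
    thr_last = np.r_[scores[order][1:] != scores[order][:-1], True]
    curve = pd.DataFrame({
        "threshold": np.r_[np.inf, scores[order][thr_last]],
        "fpr": np.r_[0.0, fps[thr_last] / n0],
        "tpr": np.r_[0.0, tps[thr_last] / n1],
    })
    return float(auc), curve
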