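"""Three-way partition of regions by what drives their entropy change.

Regional entropy changes split into three groups: regions whose change
follows connectivity strength quadratically (S1 strongly, S2 weakly) and
regions whose change follows receptor density linearly (R1). The partition
is seeded from a prior set of regions (anatomically, the occipital cortex),
grown by residual comparison, and refined by random search maximising the
R^2 of a grouped linear model.

The grouped model has 7 terms by default: a shared constant plus, for each
group, one strength term (quadratic for the strength-driven groups, linear
for R1) and one density term. A fuller 12-term interaction variant (per-group
intercept, linear and quadratic strength, and density) is available via
``design="full"``.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import statsmodels.api as sm

from .params import Connectome, InvalidParameterError

__all__ = [
    "RegionFeatures",
    "RegionPartition",
    "PartitionModelFit",
    "node_strength",
    "seed_partition",
    "optimize_partition",
    "refine_partition",
    "fit_partition_model",
]

GROUPS = ("S1", "S2", "R1")


@dataclass(frozen=True)
class RegionFeatures:
    """Per-region covariates: strength, receptor density, entropy change."""

    strength: np.ndarray
    density: np.ndarray
    delta_h: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        s = np.asarray(self.strength, dtype=float)
        d = np.asarray(self.density, dtype=float)
        dh = np.asarray(self.delta_h, dtype=float)
        if not (len(s) == len(d) == len(dh)):
            raise InvalidParameterError("feature vectors must have equal length")
        if np.any(s < 0):
            raise InvalidParameterError("strength must be nonnegative")
        object.__setattr__(self, "strength", s)
        object.__setattr__(self, "density", d)
        object.__setattr__(self, "delta_h", dh)
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"R{i:03d}" for i in range(len(s)))
            )
        elif len(self.labels) != len(s):
            raise InvalidParameterError("label count must match features")
        else:
            object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_regions(self) -> int:
        return len(self.strength)


@dataclass(frozen=True)
class RegionPartition:
    """Exhaustive, exclusive assignment of regions to S1 / S2 / R1."""

    labels: np.ndarray  # array of "S1" | "S2" | "R1"
    prior: tuple[str, ...] = ()
    n_iterations: int = 0

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=object)
        unknown = set(lab) - set(GROUPS)
        if unknown:
            raise InvalidParameterError(f"unknown group labels: {sorted(unknown)}")
        object.__setattr__(self, "labels", lab)

    def members(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.labels == group)


@dataclass(frozen=True)
class PartitionModelFit:
    """Grouped linear model of delta_h: coefficients, overall/per-group R^2."""

    coefficients: dict[str, float]
    r_squared: float
    per_group_r_squared: dict[str, float]
    residuals: np.ndarray
    rank_deficient: bool


def node_strength(connectome: Connectome) -> np.ndarray:
    """Connectivity strength: sum of weighted links incident to each region."""
    return connectome.strength()


def _quadratic_residuals(x: np.ndarray, y: np.ndarray, x_all, y_all) -> np.ndarray:
    """Squared residuals of every point under a quadratic OLS fit to (x, y)."""
    with warnings.catch_warnings():
        # tiny prior sets under-determine the quadratic; least squares still
        # yields a usable seed curve
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        coef = np.polyfit(x, y, 2)
    return (y_all - np.polyval(coef, x_all)) ** 2


def _linear_residuals(x: np.ndarray, y: np.ndarray, x_all, y_all) -> np.ndarray:
    coef = np.polyfit(x, y, 1)
    return (y_all - np.polyval(coef, x_all)) ** 2


def seed_partition(
    features: RegionFeatures,
    prior_regions: set[str] | list[str],
) -> RegionPartition:
    """Seed the strength group from a prior set and grow it by residuals.

    The prior regions anchor a quadratic fit of delta_h against strength; the
    non-prior regions anchor a linear fit of delta_h against receptor
    density. Each non-prior region joins S1 when its squared residual under
    the quadratic strength fit is lower than under the linear density fit;
    the rest are provisionally labelled S2 (split into S2/R1 later by
    :func:`optimize_partition`).
    """
    prior = set(prior_regions)
    if not prior:
        raise InvalidParameterError("prior set must be non-empty")
    unknown = prior - set(features.labels)
    if unknown:
        raise InvalidParameterError(f"unknown prior regions: {sorted(unknown)}")
    idx = {lab: i for i, lab in enumerate(features.labels)}
    prior_mask = np.zeros(features.n_regions, dtype=bool)
    prior_mask[[idx[lab] for lab in prior]] = True

    s, d, y = features.strength, features.density, features.delta_h
    res_quad = _quadratic_residuals(s[prior_mask], y[prior_mask], s, y)
    if prior_mask.all():
        labels = np.full(features.n_regions, "S1", dtype=object)
        return RegionPartition(labels=labels, prior=tuple(sorted(prior)))
    res_lin = _linear_residuals(d[~prior_mask], y[~prior_mask], d, y)

    labels = np.where(res_quad < res_lin, "S1", "S2").astype(object)
    labels[prior_mask] = "S1"
    return RegionPartition(labels=labels, prior=tuple(sorted(prior)))


def _group_predictions(
    features: RegionFeatures, coefficients: dict[str, float]
) -> dict[str, np.ndarray]:
    """Predicted delta_h for every region under each group's fitted curve."""
    s, d = features.strength, features.density
    const = coefficients.get("const", 0.0)
    preds = {}
    for g in GROUPS:
        key = g.lower()
        s_term = s**2 if g in ("S1", "S2") else s
        preds[g] = (
            const
            + coefficients.get(f"{key}_strength", 0.0) * s_term
            + coefficients.get(f"{key}_density", 0.0) * d
        )
    return preds


def refine_partition(
    features: RegionFeatures,
    init: RegionPartition,
    max_iter: int = 50,
    design: str = "seven_term",
) -> RegionPartition:
    """EM-style relabelling: fit the grouped model, move each free region to
    the group whose fitted curve predicts it best, refit, repeat.

    Regions in the prior set stay pinned to S1. Both half-steps minimise the
    squared error, so the grouped-model R^2 is non-decreasing; iteration
    stops at a fixed point or ``max_iter``.
    """
    labels = init.labels.copy()
    idx = {lab: i for i, lab in enumerate(features.labels)}
    pinned = np.zeros(features.n_regions, dtype=bool)
    pinned[[idx[lab] for lab in init.prior if lab in idx]] = True
    y = features.delta_h
    for _ in range(max_iter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_partition_model(features, RegionPartition(labels=labels),
                                      design=design)
        preds = _group_predictions(features, fit.coefficients)
        errs = np.column_stack([np.abs(y - preds[g]) for g in GROUPS])
        new = np.asarray(GROUPS, dtype=object)[errs.argmin(axis=1)]
        new[pinned] = "S1"
        if np.array_equal(new, labels):
            break
        labels = new
    return RegionPartition(labels=labels, prior=init.prior,
                           n_iterations=init.n_iterations)


def optimize_partition(
    features: RegionFeatures,
    init: RegionPartition,
    n_iter: int = 2000,
    rng: np.random.Generator | int | None = None,
    max_stall: int = 500,
    design: str = "seven_term",
    refine: bool = True,
) -> RegionPartition:
    """Random-search split of the non-S1 regions into S2 and R1.

    Proposals relabel each non-S1 region independently (R1 with a probability
    drawn fresh per proposal); a proposal is accepted only if it strictly
    improves the grouped-model R^2. Stops after ``n_iter`` proposals or
    ``max_stall`` consecutive non-improvements, then (by default) polishes
    the result with :func:`refine_partition`, keeping the polished labels
    only when they score at least as well. Deterministic given the rng seed;
    S1 membership is changed only by the refinement stage, and prior regions
    never move.
    """
    if n_iter < 1:
        raise InvalidParameterError("n_iter must be >= 1")
    rng = np.random.default_rng(rng)
    labels = init.labels.copy()
    free = np.flatnonzero(labels != "S1")

    def score(lab) -> float:
        with warnings.catch_warnings():
            # proposals may empty a group; that is a legitimate candidate
            warnings.simplefilter("ignore")
            return fit_partition_model(features, RegionPartition(labels=lab),
                                       design=design).r_squared

    best = labels.copy()
    best_score = score(labels)
    stall = 0
    it = 0
    for it in range(1, n_iter):
        if free.size == 0 or stall >= max_stall:
            break
        p_r1 = rng.uniform(0.1, 0.9)
        proposal = best.copy()
        proposal[free] = np.where(rng.random(free.size) < p_r1, "R1", "S2")
        sc = score(proposal)
        if sc > best_score:
            best, best_score = proposal, sc
            stall = 0
        else:
            stall += 1
    n_iterations = it if free.size else 0

    def as_partition(lab) -> RegionPartition:
        return RegionPartition(labels=lab, prior=init.prior,
                               n_iterations=n_iterations)

    result = as_partition(best)
    if refine:
        # polish from several starts; the canonicalise-then-refine pass
        # escapes the near-symmetric swapped optimum of the grouped model
        candidates = [result]
        for start in (result, as_partition(init.labels.copy())):
            polished = refine_partition(features, start, design=design)
            candidates.append(polished)
            swapped = _canonicalize_s2_r1(features, polished)
            candidates.append(refine_partition(features, swapped, design=design))
        scores = [score(c.labels) for c in candidates]
        result = candidates[int(np.argmax(scores))]
        if scores[int(np.argmax(scores))] < best_score:
            result = as_partition(best)
    return _canonicalize_s2_r1(features, result)


def _within_group_affinity(features, mask) -> float:
    """How much better strength (quadratic) explains a group than density."""
    if mask.sum() < 3:
        return 0.0
    y = features.delta_h[mask]
    if np.ptp(y) == 0:
        return 0.0

    def safe_corr(x):
        if np.ptp(x) == 0:
            return 0.0
        return abs(np.corrcoef(x, y)[0, 1])

    return safe_corr(features.strength[mask] ** 2) - safe_corr(
        features.density[mask]
    )


def _canonicalize_s2_r1(
    features: RegionFeatures, partition: RegionPartition
) -> RegionPartition:
    """Fix the S2/R1 naming by what drives each group.

    The grouped model is nearly symmetric under exchanging the two non-prior
    group labels (each group carries both a strength and a density term), so
    the optimiser identifies the split but not which side is which. The
    names carry the meaning: S2 is the strength-driven side, R1 the
    receptor-driven side, decided by within-group correlations.
    """
    labels = partition.labels
    s2 = labels == "S2"
    r1 = labels == "R1"
    if not s2.any() or not r1.any():
        return partition
    if _within_group_affinity(features, s2) < _within_group_affinity(features, r1):
        swapped = labels.copy()
        swapped[s2] = "R1"
        swapped[r1] = "S2"
        return RegionPartition(labels=swapped, prior=partition.prior,
                               n_iterations=partition.n_iterations)
    return partition


def _design_matrix(
    features: RegionFeatures, partition: RegionPartition, design: str
) -> tuple[np.ndarray, list[str]]:
    s, d = features.strength, features.density
    cols: list[np.ndarray] = [np.ones(features.n_regions)]
    names = ["const"]
    for g in GROUPS:
        mask = (partition.labels == g).astype(float)
        if design == "seven_term":
            # one strength term per group (quadratic for the strength-driven
            # groups, linear for R1) and one density term per group
            s_term = s**2 if g in ("S1", "S2") else s
            cols += [mask * s_term, mask * d]
            names += [f"{g.lower()}_strength", f"{g.lower()}_density"]
        elif design == "full":
            cols += [mask, mask * s, mask * s**2, mask * d]
            names += [
                f"{g.lower()}_const", f"{g.lower()}_strength",
                f"{g.lower()}_strength2", f"{g.lower()}_density",
            ]
        else:
            raise InvalidParameterError(f"unknown design: {design!r}")
    if design == "full":
        cols, names = cols[1:], names[1:]  # per-group intercepts replace the constant
    return np.column_stack(cols), names


def fit_partition_model(
    features: RegionFeatures,
    partition: RegionPartition,
    design: str = "seven_term",
) -> PartitionModelFit:
    """OLS fit of delta_h on the grouped strength/density design.

    Empty groups contribute zero columns, which are dropped with a warning.
    Returns the overall R^2, per-group R^2 (computed from the global
    predictions restricted to each group's own observations), and residuals.
    """
    if len(partition.labels) != features.n_regions:
        raise InvalidParameterError("partition length must match features")
    X, names = _design_matrix(features, partition, design)
    keep = ~np.all(X == 0, axis=0)
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"empty groups dropped terms: {dropped}", stacklevel=2)
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    y = features.delta_h
    model = sm.OLS(y, X).fit()
    rank_deficient = bool(np.linalg.matrix_rank(X) < X.shape[1])
    pred = model.predict(X)
    resid = y - pred
    per_group = {}
    for g in GROUPS:
        mask = partition.labels == g
        if mask.sum() < 2:
            per_group[g] = float("nan")
            continue
        sst = ((y[mask] - y[mask].mean()) ** 2).sum()
        ssr = (resid[mask] ** 2).sum()
        per_group[g] = float(1.0 - ssr / sst) if sst > 0 else float("nan")
    return PartitionModelFit(
        coefficients={n: float(v) for n, v in zip(names, model.params)},
        r_squared=float(model.rsquared),
        per_group_r_squared=per_group,
        residuals=resid,
        rank_deficient=rank_deficient,
    )
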