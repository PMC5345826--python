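"""Synthetic lognormal communities and the benchmark experiments.

The generator emulates a two-environment marker-gene survey: D taxa on a
fixed random binary tree, absolute abundances N_ij with ln N_ij i.i.d.
Normal(mu, sigma), and a balanced binary environment covariate.  Effects are
clade-level fold changes: every member of a randomly chosen clade is
multiplied by a fold in one environment.  Defaults are D = 50 taxa,
20 samples per environment, mu = 8, sigma = 0.5.

Three experiments are built on the generator:

* ``power_experiment`` — can the method find the affected clade(s)?  One
  clade with fold a in {1.5, 3, 6}, or three disjoint clades with folds
  {pi^b, 0.5^b, exp(-b)} for b in {1, 2, 5}, each in a random environment.
  Scores the greedy factorization against the rooted-ILR baseline (top
  deviance-ranked coordinates) and compares variance explained.
* ``stopping_experiment`` — calibration of the KS stopping rule: M clades
  with lognormal(0, 3) folds; the estimated factor count should be a
  conservative estimate of M.
* ``rooted_ilr_correlation_demo`` — shows that a single clade effect leaks
  into every rooted-ILR coordinate on the path from the clade to the root.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import RegressionSpec, _gaussian_fit_stats, phylofactorize
from .ilr import rooted_ilr_transform
from .io_prep import CompositionTable, close_to_composition
from .phylo_tree import Phylogeny, rooted_sbp

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "ExperimentOutcome",
    "random_tree",
    "eligible_clades",
    "draw_clades",
    "simulate_community",
    "apply_clade_effects",
    "to_composition",
    "power_experiment",
    "stopping_experiment",
    "rooted_ilr_correlation_demo",
]

ENVIRONMENTS = ("env1", "env2")
#: Fold set for the 3-clade design at intensity b.
TRIPLE_FOLDS = lambda b: (np.pi**b, 0.5**b, np.exp(-b))  # noqa: E731


@dataclass
class SimulationConfig:
    """Study conditions for one simulated community experiment."""

    D: int = 50
    p_per_group: int = 20
    mu: float = 8.0
    sigma: float = 0.5
    n_clades: int = 1
    #: ("single", a) for one clade at fold a; ("triple", b) for three clades
    #: at folds {pi^b, 0.5^b, exp(-b)}; ("lognormal", sd) for n_clades folds
    #: with ln(fold) ~ Normal(0, sd).
    fold_spec: tuple[str, float] = ("single", 6.0)
    replicates: int = 500
    seed: int = 0
    min_clade_size: int = 2
    max_clade_frac: float = 0.5

    def __post_init__(self):
        if self.D < 2 or self.p_per_group < 1 or self.sigma < 0:
            raise ValueError("invalid simulation config")
        kind, value = self.fold_spec
        if kind not in ("single", "triple", "lognormal"):
            raise ValueError(f"unknown fold_spec kind {kind!r}")
        if kind != "lognormal" and value <= 0:
            raise ValueError("fold parameters must be positive")


@dataclass
class SimulatedDataset:
    """Absolute abundances plus the ground truth that generated them."""

    abundances: pd.DataFrame  # taxa x samples, strictly positive
    environment: pd.Series  # sample id -> "env1" / "env2"
    tree: Phylogeny
    clades: list[frozenset[str]] = field(default_factory=list)
    folds: list[float] = field(default_factory=list)
    fold_environments: list[str] = field(default_factory=list)


@dataclass
class ExperimentOutcome:
    """Per-replicate metrics and a mean/quantile summary."""

    per_replicate: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        group_cols = [c for c in ("a", "b", "M") if c in self.per_replicate.columns]
        metrics = [c for c in self.per_replicate.columns if c not in group_cols + ["replicate"]]
        grouped = self.per_replicate.groupby(group_cols) if group_cols else self.per_replicate
        agg = grouped[metrics].agg(["mean", lambda x: x.quantile(0.025), lambda x: x.quantile(0.975)])
        agg.columns = [f"{m}_{s}" for m, s in
                       ((m, {"mean": "mean", "<lambda_0>": "q025", "<lambda_1>": "q975"}[s])
                        for m, s in agg.columns)]
        return agg


def random_tree(D: int, seed: int) -> Phylogeny:
    """Random binary tree on D labeled tips, deterministic given the seed.

    Built by repeatedly joining two uniformly chosen subtrees, giving a
    rooted binary topology (usable both rooted, for the rooted ILR, and
    unrooted, for factorization).
    """
    if D < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    clusters = [f"t{i + 1:03d}" for i in range(D)]
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        merged = f"({clusters[i]},{clusters[j]})"
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return Phylogeny.from_newick(clusters[0] + ";")


def eligible_clades(
    tree: Phylogeny, min_size: int = 2, max_size: int | None = None
) -> list[frozenset[str]]:
    """Clades (child-side tip sets of edges) with size in [min_size, max_size].

    The default bounds [2, D/2] rule out single tips and effects spanning
    more than half the community, which would be indistinguishable from a
    complementary effect on the other half.
    """
    if max_size is None:
        max_size = tree.n_tips // 2
    return [c for c in tree.rooted_clades() if min_size <= len(c) <= max_size]


def draw_clades(
    tree: Phylogeny,
    n: int,
    rng: np.random.Generator,
    min_size: int = 2,
    max_size: int | None = None,
    disjoint: bool = True,
    max_tries: int = 1000,
) -> list[frozenset[str]]:
    """Uniformly draw ``n`` (by default disjoint) clades of the tree."""
    pool = eligible_clades(tree, min_size, max_size)
    if not pool:
        raise ValueError("no eligible clades")
    for _ in range(max_tries):
        chosen: list[frozenset[str]] = []
        remaining = list(pool)
        ok = True
        for _ in range(n):
            if not remaining:
                ok = False
                break
            clade = remaining[rng.integers(len(remaining))]
            chosen.append(clade)
            if disjoint:
                remaining = [c for c in remaining if not (c & clade)]
        if ok:
            return chosen
    raise RuntimeError(f"could not draw {n} disjoint clades in {max_tries} tries")


def simulate_community(
    config: SimulationConfig, tree: Phylogeny | None = None, rng=None
) -> SimulatedDataset:
    """Baseline community (no effects): ln N_ij ~ Normal(mu, sigma)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if tree is None:
        tree = random_tree(config.D, config.seed)
    if tree.n_tips != config.D:
        raise ValueError("tree size does not match config.D")
    n = 2 * config.p_per_group
    N = np.exp(rng.normal(config.mu, config.sigma, size=(config.D, n)))
    samples = [f"s{j + 1:03d}" for j in range(n)]
    abund = pd.DataFrame(N, index=tree.tips, columns=samples)
    env = pd.Series(
        [ENVIRONMENTS[0]] * config.p_per_group + [ENVIRONMENTS[1]] * config.p_per_group,
        index=samples,
        name="environment",
    )
    return SimulatedDataset(abund, env, tree)


def apply_clade_effects(
    data: SimulatedDataset, clades, folds, environments
) -> SimulatedDataset:
    """Multiply each clade's members by its fold in its designated environment."""
    if not (len(clades) == len(folds) == len(environments)):
        raise ValueError("clades, folds and environments must align")
    abund = data.abundances.copy()
    for clade, fold, env in zip(clades, folds, environments):
        clade = frozenset(clade)
        if not data.tree.is_clade(clade):
            raise ValueError(f"not a clade of the tree: {sorted(clade)[:5]}...")
        if fold <= 0:
            raise ValueError("folds must be positive")
        cols = data.environment[data.environment == env].index
        abund.loc[sorted(clade), cols] *= fold
    return SimulatedDataset(
        abund,
        data.environment,
        data.tree,
        data.clades + [frozenset(c) for c in clades],
        data.folds + list(folds),
        data.fold_environments + list(environments),
    )


def to_composition(data: SimulatedDataset) -> CompositionTable:
    """Close absolute abundances to relative abundances (the analysis scale)."""
    return close_to_composition(data.abundances)


# ---------------------------------------------------------------------------
# scoring helpers


def _rooted_ilr_ranked(comp, tree, X, spec):
    """Rooted-ILR coordinates ranked by explained SS (descending).

    Returns (ordered list of (R, S) rows, ordered explained SS).
    """
    sbp = rooted_sbp(tree)
    balances = rooted_ilr_transform(comp, sbp).to_numpy()
    A, _ = spec.build_design(X.loc[list(comp.samples)])
    Q, _ = np.linalg.qr(A)
    ess, _ = _gaussian_fit_stats(balances, Q, A.shape[1])
    order = np.argsort(-ess, kind="stable")
    return [sbp[i] for i in order], ess[order]


def _identifies_clade(side_pair, clades) -> bool:
    R, S = side_pair
    return any(R == c or S == c for c in clades)


def _replicate_metrics(dataset: SimulatedDataset, top_k: int) -> dict:
    comp = to_composition(dataset)
    X = dataset.environment.to_frame()
    spec = RegressionSpec(("environment",))
    result = phylofactorize(comp, dataset.tree, spec, X, stop=top_k)
    pf_hits = [
        _identifies_clade((f.side_R, f.side_S), dataset.clades) for f in result.factors
    ]
    pf_ve = sum(f.candidate.objective for f in result.factors)
    rows, ess = _rooted_ilr_ranked(comp, dataset.tree, X, spec)
    ilr_hits = [_identifies_clade(rows[i], dataset.clades) for i in range(top_k)]
    return {
        "pf_score": float(np.mean(pf_hits)) if pf_hits else 0.0,
        "ilr_score": float(np.mean(ilr_hits)),
        "pf_var_explained": float(pf_ve),
        "ilr_var_explained": float(ess[:top_k].sum()),
    }


def power_experiment(config: SimulationConfig) -> ExperimentOutcome:
    """Compare factorization and rooted ILR on communities with known effects.

    Single-clade design: top-1 scores; triple-clade design: top-3 scores and
    the variance-explained comparison.  The tree is fixed across replicates.
    """
    kind, value = config.fold_spec
    if kind not in ("single", "triple"):
        raise ValueError("power_experiment needs a 'single' or 'triple' fold_spec")
    n_clades = 1 if kind == "single" else 3
    top_k = n_clades
    seq = np.random.SeedSequence(config.seed)
    tree_seed = int(seq.generate_state(1)[0] % (2**31))
    tree = random_tree(config.D, tree_seed)
    streams = seq.spawn(config.replicates)
    rows = []
    for r, child in enumerate(streams):
        rng = np.random.default_rng(child)
        base = simulate_community(config, tree, rng)
        clades = draw_clades(
            tree, n_clades, rng, config.min_clade_size,
            int(config.max_clade_frac * config.D),
        )
        if kind == "single":
            folds = [value]
            envs = [ENVIRONMENTS[1]]  # the second environment, by construction
        else:
            folds = list(TRIPLE_FOLDS(value))
            envs = [ENVIRONMENTS[rng.integers(2)] for _ in range(3)]
        data = apply_clade_effects(base, clades, folds, envs)
        metrics = _replicate_metrics(data, top_k)
        metrics["replicate"] = r
        metrics[{"single": "a", "triple": "b"}[kind]] = value
        rows.append(metrics)
    return ExperimentOutcome(pd.DataFrame(rows))


def stopping_experiment(
    M_values,
    replicates: int,
    seed: int,
    D: int = 50,
    p_per_group: int = 20,
    mu: float = 8.0,
    sigma: float = 0.5,
    fold_sigma: float = 3.0,
    ks_threshold: float = 0.05,
) -> ExperimentOutcome:
    """KS-rule calibration: estimated factor count K vs true clade count M.

    For each M, ``replicates`` communities carry M disjoint clades with
    ln(fold) ~ Normal(0, fold_sigma), each in a random environment; the
    factorization runs under the KS stopping rule and K is recorded.
    """
    M_values = list(M_values)
    if replicates < 1 or any(m < 0 for m in M_values):
        raise ValueError("invalid M range or replicate count")
    seq = np.random.SeedSequence(seed)
    tree_seed = int(seq.generate_state(1)[0] % (2**31))
    tree = random_tree(D, tree_seed)
    spec = RegressionSpec(("environment",))
    streams = seq.spawn(len(M_values) * replicates)
    rows = []
    for idx, child in enumerate(streams):
        M = M_values[idx // replicates]
        r = idx % replicates
        rng = np.random.default_rng(child)
        config = SimulationConfig(
            D=D, p_per_group=p_per_group, mu=mu, sigma=sigma,
            n_clades=M, fold_spec=("lognormal", fold_sigma),
        )
        base = simulate_community(config, tree, rng)
        if M > 0:
            clades = draw_clades(tree, M, rng, config.min_clade_size,
                                 int(config.max_clade_frac * D))
            folds = np.exp(rng.normal(0.0, fold_sigma, size=M))
            envs = [ENVIRONMENTS[rng.integers(2)] for _ in range(M)]
            data = apply_clade_effects(base, clades, folds, envs)
        else:
            data = base
        result = phylofactorize(
            to_composition(data), tree, spec, data.environment.to_frame(),
            stop="ks", ks_threshold=ks_threshold,
        )
        rows.append({"M": M, "replicate": r, "K": result.n_factors})
    return ExperimentOutcome(pd.DataFrame(rows))


def rooted_ilr_correlation_demo(
    a: float = 6.0,
    D: int = 50,
    p_per_group: int = 30,
    seed: int = 0,
    mu: float = 8.0,
    sigma: float = 0.5,
) -> tuple[pd.DataFrame, float]:
    """Correlation of every rooted-ILR coordinate with the environment.

    A single clade is up-weighted by fold ``a`` in the second environment;
    the returned frame flags coordinates on the path from that clade to the
    root, and the second value is the baseline (mean |correlation| over
    off-path coordinates).  With a strong effect the root-path coordinates
    stand out above the baseline even though only one clade changed.
    """
    rng = np.random.default_rng(seed)
    tree = random_tree(D, seed)
    config = SimulationConfig(D=D, p_per_group=p_per_group, mu=mu, sigma=sigma,
                              fold_spec=("single", a))
    base = simulate_community(config, tree, rng)
    clade = draw_clades(tree, 1, rng)[0]
    data = apply_clade_effects(base, [clade], [a], [ENVIRONMENTS[1]])
    comp = to_composition(data)
    sbp = rooted_sbp(tree)
    balances = rooted_ilr_transform(comp, sbp).to_numpy()
    env = (data.environment == ENVIRONMENTS[1]).to_numpy(dtype=float)
    env_c = env - env.mean()
    rows = []
    for i, (R, S) in enumerate(sbp):
        b = balances[i] - balances[i].mean()
        denom = np.sqrt((b @ b) * (env_c @ env_c))
        corr = abs(b @ env_c / denom) if denom > 0 else 0.0
        descendants = R | S
        on_path = clade <= descendants and descendants != clade
        rows.append({"coordinate": i, "abs_correlation": corr, "on_root_path": on_path})
    df = pd.DataFrame(rows)
    off = df.loc[~df.on_root_path, "abs_correlation"]
    baseline = float(off.mean()) if len(off) else float("nan")
    return df, baseline
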