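"""Mechanism-of-action estimation from 12-steroid fold-change profiles.

A compound's action on steroidogenesis is summarized by eight relative
enzyme-activity multipliers (CYP11A1, CYP17H, CYP17L, HSD3B2, CYP21A2,
CYP11B1, CYP11B2, HSD17B3; CYP19A1 is held at baseline).  Given the
measured fold changes (treated/control) of the 12 LC-MS steroids in the
medium at 72 h, the multipliers are estimated by a two-step hybrid:

1. a real-coded genetic algorithm with REX crossover (children sampled
   around the parent centroid) and JGG generation alternation (only the
   sampled parents are replaced, by the best children), searching
   log10-activity space within [1/100, 100];
2. a Levenberg-Marquardt local search polishing the GA optimum.

The fitness is the normalized sum of squared fold-change residuals,
``sum_i ((FC_obs,i - FC_sim,i) / FC_obs,i)^2`` over steroids quantified in
the observation (below-LLOQ steroids are excluded, never imputed); a raw
unnormalized variant is available behind a switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ttest_ind

from . import _core
from .parameters import KineticParameterSet, default_initial_state_vector, default_parameters
from .simulate import IntegratorConfig
from .species import ENZYMES, LCMS_STEROIDS, MOA_ENZYMES, medium_index

ACTIVITY_BOUNDS = (1.0 / 100.0, 100.0)
_LOG_BOUNDS = (np.log10(ACTIVITY_BOUNDS[0]), np.log10(ACTIVITY_BOUNDS[1]))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class EnzymeActivityProfile:
    """Relative activities of the 8 estimated enzymes (1 = unperturbed)."""

    def __init__(self, values):
        if isinstance(values, dict):
            unknown = set(values) - set(MOA_ENZYMES)
            if unknown:
                raise KeyError(f"unknown enzymes {sorted(unknown)}")
            vec = np.array([values.get(e, 1.0) for e in MOA_ENZYMES], float)
        else:
            vec = np.asarray(values, dtype=float)
        if vec.shape != (len(MOA_ENZYMES),):
            raise ValueError(f"expected {len(MOA_ENZYMES)} activities")
        lo, hi = ACTIVITY_BOUNDS
        if np.any(vec < lo) or np.any(vec > hi):
            raise ValueError(f"activities must lie in [{lo}, {hi}]")
        self.values = vec

    def __getitem__(self, enzyme: str) -> float:
        return float(self.values[MOA_ENZYMES.index(enzyme)])

    def to_dict(self) -> dict[str, float]:
        return dict(zip(MOA_ENZYMES, map(float, self.values)))

    def full_activities(self) -> np.ndarray:
        """9-vector in model enzyme order, CYP19A1 fixed at 1."""
        full = np.ones(len(ENZYMES))
        for e, v in zip(MOA_ENZYMES, self.values):
            full[ENZYMES.index(e)] = v
        return full

    @classmethod
    def unperturbed(cls) -> "EnzymeActivityProfile":
        return cls(np.ones(len(MOA_ENZYMES)))

    def inhibition_percent(self) -> dict[str, float]:
        """(1 - activity) x 100 per enzyme; negative values mean activation."""
        return {e: (1.0 - v) * 100.0 for e, v in self.to_dict().items()}

    def __repr__(self) -> str:  # pragma: no cover
        parts = ", ".join(f"{e}={v:.3g}" for e, v in self.to_dict().items())
        return f"EnzymeActivityProfile({parts})"


class FoldChangeProfile:
    """Treated/control medium-concentration ratios of the 12 LC-MS steroids."""

    def __init__(self, values, below_lloq=None):
        if isinstance(values, dict):
            unknown = set(values) - set(LCMS_STEROIDS)
            if unknown:
                raise KeyError(f"unknown steroids {sorted(unknown)}")
            vec = np.array([values[s] for s in LCMS_STEROIDS], float)
        else:
            vec = np.asarray(values, dtype=float)
        if vec.shape != (len(LCMS_STEROIDS),):
            raise ValueError(f"expected {len(LCMS_STEROIDS)} fold changes")
        if below_lloq is None:
            below_lloq = np.zeros(len(LCMS_STEROIDS), dtype=bool)
        flags = np.asarray(below_lloq, dtype=bool)
        if flags.shape != vec.shape:
            raise ValueError("flag vector must match the fold-change vector")
        if np.any(vec[~flags] <= 0) or not np.all(np.isfinite(vec[~flags])):
            raise ValueError("quantified fold changes must be positive finite")
        self.values = vec
        self.below_lloq = flags

    @property
    def quantified(self) -> np.ndarray:
        return ~self.below_lloq

    def __getitem__(self, steroid: str) -> float:
        return float(self.values[LCMS_STEROIDS.index(steroid)])

    def to_frame(self, compound: str = "", concentration: float = np.nan
                 ) -> pd.DataFrame:
        return pd.DataFrame({
            "compound": compound, "concentration": concentration,
            "steroid": LCMS_STEROIDS, "fold_change": self.values,
            "below_lloq": self.below_lloq,
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FoldChangeProfile":
        sub = frame.set_index("steroid")
        return cls(np.array([sub.loc[s, "fold_change"] for s in LCMS_STEROIDS]),
                   np.array([bool(sub.loc[s, "below_lloq"])
                             for s in LCMS_STEROIDS]))

    def __repr__(self) -> str:  # pragma: no cover
        n = int(self.below_lloq.sum())
        return f"FoldChangeProfile(12 steroids, {n} censored)"


@dataclass(frozen=True)
class MoAConfig:
    """Settings of the two-step GA + local-search estimator."""

    max_generations: int = 1000
    population_size: int = 100
    n_parents: int = 6
    n_children: int = 25
    termination_fitness: float = 0.1
    seed: int = 0
    duplicate: bool = False
    rex_distribution: str = "uniform"  # or "normal"
    normalized: bool = True            # raw-SSR objective when False
    local_search: bool = True
    lm_max_nfev: int = 200

    def __post_init__(self):
        if min(self.max_generations, self.population_size, self.n_parents,
               self.n_children) < 1:
            raise ValueError("GA sizes must be positive integers")
        if self.n_parents < 2:
            raise ValueError("REX needs at least 2 parents")
        if self.n_children < self.n_parents - 1:
            raise ValueError("need n_children >= n_parents - 1 for REX/JGG")
        if self.n_parents > self.population_size:
            raise ValueError("cannot select more parents than the population")
        if self.rex_distribution not in ("uniform", "normal"):
            raise ValueError("rex_distribution must be 'uniform' or 'normal'")


# ---------------------------------------------------------------------------
# Baseline model context
# ---------------------------------------------------------------------------


class BaselineModel:
    """A calibrated control condition against which perturbations are scored."""

    def __init__(self,
                 params: KineticParameterSet | None = None,
                 initial_state: np.ndarray | None = None,
                 config: IntegratorConfig | None = None):
        self.params = params if params is not None else default_parameters()
        self.config = config or IntegratorConfig()
        self.initial_state = (np.asarray(initial_state, float)
                              if initial_state is not None
                              else default_initial_state_vector())
        base, ok = self._batch(np.ones((1, len(ENZYMES))))
        if not ok[0]:
            raise FloatingPointError("baseline simulation diverged")
        self.baseline_final = base[0]
        self.baseline_medium = np.array(
            [self.baseline_final[medium_index(s)] for s in LCMS_STEROIDS])

    def _batch(self, activities: np.ndarray):
        m = activities.shape[0]
        Y0 = np.tile(self.initial_state, (m, 1))
        P = np.tile(self.params.to_vector(), (m, 1))
        return _core.final_states_ensemble(
            Y0, P, np.ascontiguousarray(activities, dtype=np.float64),
            self.params.geometry.to_vector(), self.params.dilution,
            self.config.duration, self.config.step_constant,
            self.config.dt_min, self.config.dt_max)

    def final_states(self, activity_matrix: np.ndarray):
        """72-h states for a batch of 8-vector activity profiles."""
        A = np.asarray(activity_matrix, dtype=float)
        full = np.ones((A.shape[0], len(ENZYMES)))
        cols = [ENZYMES.index(e) for e in MOA_ENZYMES]
        full[:, cols] = A
        return self._batch(full)

    def predict_foldchange(self, activities) -> FoldChangeProfile:
        """Simulated 72-h fold-change profile of an activity perturbation."""
        if isinstance(activities, EnzymeActivityProfile):
            act = activities.values
        else:
            act = np.asarray(activities, dtype=float)
        finals, ok = self.final_states(act[None, :])
        if not ok[0]:
            raise FloatingPointError("perturbed simulation diverged")
        med = np.array([finals[0, medium_index(s)] for s in LCMS_STEROIDS])
        undefined = self.baseline_medium <= 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = med / self.baseline_medium
        fc[undefined] = 1.0
        return FoldChangeProfile(fc, below_lloq=undefined)

    def foldchange_matrix(self, activity_matrix: np.ndarray) -> np.ndarray:
        """(m, 12) fold-change matrix for a batch; diverged rows become inf."""
        finals, ok = self.final_states(activity_matrix)
        idx = [medium_index(s) for s in LCMS_STEROIDS]
        fc = finals[:, idx] / self.baseline_medium
        fc[~ok] = np.inf
        return fc


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------


def moa_objective(observed: FoldChangeProfile,
                  predicted,
                  normalized: bool = True) -> float:
    """Fold-change misfit over the steroids quantified in the observation."""
    mask = observed.quantified
    if not mask.any():
        raise ValueError("all steroids censored; objective undefined")
    sim = predicted.values if isinstance(predicted, FoldChangeProfile) \
        else np.asarray(predicted, dtype=float)
    r = observed.values[mask] - sim[mask]
    if normalized:
        r = r / observed.values[mask]
    return float(np.sum(r * r))


# ---------------------------------------------------------------------------
# REX / JGG genetic algorithm
# ---------------------------------------------------------------------------


def rex_crossover(parents: np.ndarray, n_children: int,
                  rng: np.random.Generator,
                  distribution: str = "uniform",
                  bounds: tuple[float, float] = _LOG_BOUNDS) -> np.ndarray:
    """Real-coded ensemble crossover.

    Children are sampled around the parent centroid ``g`` as
    ``g + sum_k xi_k (p_k - g)`` with i.i.d. ``xi`` of mean 0 and variance
    ``1/(k-1)`` (uniform by default; Gaussian behind the flag), then clipped
    to the search box.
    """
    parents = np.asarray(parents, dtype=float)
    if parents.ndim != 2 or parents.shape[0] < 2:
        raise ValueError("need at least 2 parents of equal dimension")
    k = parents.shape[0]
    centroid = parents.mean(axis=0)
    spread = parents - centroid
    if distribution == "uniform":
        half = np.sqrt(3.0 / (k - 1))
        xi = rng.uniform(-half, half, size=(n_children, k))
    elif distribution == "normal":
        xi = rng.normal(0.0, np.sqrt(1.0 / (k - 1)), size=(n_children, k))
    else:
        raise ValueError("distribution must be 'uniform' or 'normal'")
    children = centroid + xi @ spread
    return np.clip(children, bounds[0], bounds[1])


def jgg_step(population: np.ndarray, fitness: np.ndarray,
             objective_batch, config: MoAConfig,
             rng: np.random.Generator,
             bounds: tuple[float, float] = _LOG_BOUNDS):
    """One just-generation-gap step.

    Samples ``n_parents`` individuals uniformly without replacement,
    produces ``n_children`` by REX, and replaces exactly the sampled parents
    with the best children; everyone else is untouched.  Returns the new
    population, its fitness, and the number of objective evaluations.
    """
    n = population.shape[0]
    idx = rng.choice(n, size=config.n_parents, replace=False)
    children = rex_crossover(population[idx], config.n_children, rng,
                             config.rex_distribution, bounds)
    f_children = np.asarray(objective_batch(children), dtype=float)
    best = np.argsort(f_children, kind="stable")[:config.n_parents]
    new_pop = population.copy()
    new_fit = fitness.copy()
    new_pop[idx] = children[best]
    new_fit[idx] = f_children[best]
    return new_pop, new_fit, config.n_children


@dataclass
class MoAResult:
    """Estimated mechanism of action for one fold-change profile."""

    activities: EnzymeActivityProfile
    fitness: float
    ga_fitness: float
    generations: int
    n_evaluations: int
    history: np.ndarray            # best fitness per generation
    converged: bool
    identifiability: dict[str, bool] = field(default_factory=dict)
    duplicate: "MoAResult | None" = None

    def agreement_with(self, other: "MoAResult") -> float:
        """Largest per-enzyme activity ratio between two runs (>= 1)."""
        a, b = self.activities.values, other.activities.values
        r = np.maximum(a / b, b / a)
        return float(np.max(r))


def _downstream_identifiability(observed: FoldChangeProfile) -> dict[str, bool]:
    """Flag enzymes whose informative product steroids are censored."""
    probes = {
        "CYP11B2": ("ALDO",),
        "HSD17B3": ("TESTO",),
        "CYP11B1": ("CORTICO", "CORT"),
    }
    flags = {e: True for e in MOA_ENZYMES}
    for enzyme, steroids in probes.items():
        idx = [LCMS_STEROIDS.index(s) for s in steroids]
        if observed.below_lloq[idx].all():
            flags[enzyme] = False
    return flags


def estimate_moa(observed: FoldChangeProfile,
                 model: BaselineModel,
                 config: MoAConfig | None = None) -> MoAResult:
    """Two-step REX/JGG GA + Levenberg-Marquardt estimate of enzyme activities.

    With ``config.duplicate`` the whole optimization runs twice from
    independent seeds as a numerical-stability check; the better run is
    returned with the other attached as ``result.duplicate``.
    """
    config = config or MoAConfig()
    if config.duplicate:
        first = estimate_moa(observed, model,
                             replace(config, duplicate=False))
        second = estimate_moa(observed, model,
                              replace(config, duplicate=False,
                                      seed=config.seed + 104729))
        primary, other = ((first, second)
                          if first.fitness <= second.fitness
                          else (second, first))
        primary.duplicate = other
        return primary

    rng = np.random.default_rng(config.seed)
    d = len(MOA_ENZYMES)
    lo, hi = _LOG_BOUNDS
    mask = observed.quantified
    if not mask.any():
        raise ValueError("all steroids censored; nothing to fit")
    obs = observed.values

    def objective_batch(X):
        fc = model.foldchange_matrix(10.0 ** np.asarray(X, float))
        r = obs[None, mask] - fc[:, mask]
        if config.normalized:
            r = r / obs[None, mask]
        out = np.sum(r * r, axis=1)
        return np.where(np.isfinite(out), out, 1e12)

    population = rng.uniform(lo, hi, size=(config.population_size, d))
    fitness = objective_batch(population)
    n_evals = config.population_size
    history = []
    converged = False
    gen = 0
    for gen in range(1, config.max_generations + 1):
        population, fitness, ne = jgg_step(population, fitness,
                                           objective_batch, config, rng)
        n_evals += ne
        best = float(fitness.min())
        history.append(best)
        if best < config.termination_fitness:
            converged = True
            break
    i_best = int(np.argmin(fitness))
    x_best = population[i_best]
    ga_fit = float(fitness[i_best])

    x_final, final_fit = x_best, ga_fit
    if config.local_search:
        def residuals(x):
            fc = model.foldchange_matrix(10.0 ** x[None, :])[0]
            r = obs[mask] - fc[mask]
            if config.normalized:
                r = r / obs[mask]
            return np.where(np.isfinite(r), r, 1e6)

        sol = least_squares(residuals, x_best, method="lm",
                            max_nfev=config.lm_max_nfev)
        x_lm = np.clip(sol.x, lo, hi)
        f_lm = float(objective_batch(x_lm[None, :])[0])
        n_evals += sol.nfev
        if f_lm <= final_fit:
            x_final, final_fit = x_lm, f_lm

    return MoAResult(
        activities=EnzymeActivityProfile(10.0 ** x_final),
        fitness=final_fit, ga_fitness=ga_fit, generations=gen,
        n_evaluations=n_evals, history=np.array(history),
        converged=converged or final_fit < config.termination_fitness,
        identifiability=_downstream_identifiability(observed))


# ---------------------------------------------------------------------------
# Supporting statistics
# ---------------------------------------------------------------------------


def welch_bonferroni(treated: np.ndarray, control: np.ndarray,
                     labels=None, alpha: float = 0.01) -> pd.DataFrame:
    """Per-species Welch t-tests with Bonferroni correction.

    ``treated``/``control`` are (n_species, n_replicates) arrays (>= 2
    replicates each).  Adjusted p is ``min(1, p * n_species)``; species are
    significant at adjusted p < ``alpha``.  A species with zero variance in
    both groups gets an undefined p and a flag.
    """
    treated = np.atleast_2d(np.asarray(treated, float))
    control = np.atleast_2d(np.asarray(control, float))
    if treated.shape[0] != control.shape[0]:
        raise ValueError("treated and control must cover the same species")
    if treated.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("need at least 2 replicates per group")
    m = treated.shape[0]
    labels = list(labels) if labels is not None else list(range(m))
    p_raw = np.empty(m)
    degenerate = np.zeros(m, dtype=bool)
    for i in range(m):
        if treated[i].var(ddof=1) == 0.0 and control[i].var(ddof=1) == 0.0:
            if np.allclose(treated[i].mean(), control[i].mean()):
                p_raw[i] = 1.0
            else:
                p_raw[i] = np.nan
                degenerate[i] = True
            continue
        p_raw[i] = ttest_ind(treated[i], control[i], equal_var=False).pvalue
    p_adj = np.minimum(p_raw * m, 1.0)
    return pd.DataFrame({
        "species": labels, "p_raw": p_raw, "p_adjusted": p_adj,
        "significant": p_adj < alpha, "zero_variance": degenerate,
    })


@dataclass
class ClusterResult:
    """Ward clustering of compound fold-change profiles."""

    linkage: np.ndarray
    distance_matrix: pd.DataFrame
    labels: list
    leaf_order: list

    def flat_clusters(self, n_clusters: int) -> dict:
        assign = hierarchy.fcluster(self.linkage, n_clusters,
                                    criterion="maxclust")
        return dict(zip(self.labels, assign.tolist()))


def cluster_profiles(profiles: pd.DataFrame,
                     sd_floor: float = 1e-12) -> ClusterResult:
    """Hierarchical Ward clustering on standardized Euclidean distances.

    ``profiles`` is a compounds x features table (typically log2 fold
    changes).  Feature variances below ``sd_floor``^2 (constant columns) are
    floored so the metric stays defined.  Deterministic leaf ordering.
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 profiles to cluster")
    X = profiles.to_numpy(dtype=float)
    variances = np.maximum(X.var(axis=0, ddof=1), sd_floor ** 2)
    condensed = pdist(X, metric="seuclidean", V=variances)
    Z = hierarchy.linkage(condensed, method="ward")
    labels = list(profiles.index)
    dm = pd.DataFrame(squareform(condensed), index=labels, columns=labels)
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(linkage=Z, distance_matrix=dm, labels=labels,
                         leaf_order=order)
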