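"""Assembly-mechanism battery: probability-weight families and the two-stage
community simulator that scores seven candidate assembly processes.

Four weight families feed the simulator:

* ``w_f`` — neutral regional occupancy frequencies (constant across samples),
* ``w_a`` — neutral regional abundance shares (constant across samples),
* ``w_d`` — dispersal weights: for sample i and taxon k, the inverse-distance
  weighted mean of the other samples' relative abundances,
  ``w_d[i,k] = sum_{j!=i} (1/d_ij) x_jk / sum_{j!=i} (1/d_ij)``,
* ``w_e`` — environmental weights: per-taxon occurrence probability from an
  RBF-kernel support-vector classifier on the soil principal components,
  calibrated to probabilities by Platt scaling (logistic regression on the
  decision scores with 5-fold cross-validation).

A simulated community for sample i draws its observed richness of taxa
without replacement with probability proportional to the occurrence rule's
weights, then assigns relative abundances from Dirichlet(alpha) with
alpha = w*/min(w*) over the chosen taxa (the same construction as the
neutral null model).  Each of the seven occurrence->abundance rule
combinations is scored by the mean Sorensen and Bray-Curtis dissimilarity of
simulated to observed communities; a smaller mean dissimilarity indicates a
better-fitting assembly process.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .nullmodel import RegionalWeights, regional_weights
from .tables import CommunityTable

__all__ = [
    "AssemblyWeights",
    "dispersal_weights",
    "environmental_weights",
    "neutral_frequency_weights",
    "neutral_abundance_weights",
    "simulate_community",
    "run_battery",
    "ProcessScore",
    "MechanismBattery",
    "BatteryResults",
    "weight_correlation",
    "PROCESSES",
]

logger = logging.getLogger(__name__)

# the seven occurrence -> abundance rule combinations
PROCESSES: tuple[tuple[str, str], ...] = (
    ("w_f", "w_a"),
    ("w_e", "w_a"),
    ("w_d", "w_a"),
    ("w_e", "w_e"),
    ("w_e", "w_d"),
    ("w_d", "w_e"),
    ("w_d", "w_d"),
)

ZERO_WEIGHT_FLOOR = 1e-6


def process_label(occurrence: str, abundance: str) -> str:
    return f"{occurrence[-1]}->{abundance[-1]}"


@dataclass
class AssemblyWeights:
    """Per-sample x taxon probability weights for one rule family."""

    kind: str  # one of w_f, w_a, w_d, w_e
    values: pd.DataFrame  # samples x taxa
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError(f"{self.kind} weights must be non-negative")


def neutral_frequency_weights(table: CommunityTable) -> AssemblyWeights:
    """w_f broadcast to every sample (rows sum to 1)."""
    w = regional_weights(table).w_f.to_numpy()
    values = pd.DataFrame(
        np.tile(w, (table.n_samples, 1)),
        index=table.sample_ids,
        columns=table.taxon_ids,
    )
    return AssemblyWeights(kind="w_f", values=values)


def neutral_abundance_weights(table: CommunityTable) -> AssemblyWeights:
    """w_a broadcast to every sample (rows sum to 1)."""
    w = regional_weights(table).w_a.to_numpy()
    values = pd.DataFrame(
        np.tile(w, (table.n_samples, 1)),
        index=table.sample_ids,
        columns=table.taxon_ids,
    )
    return AssemblyWeights(kind="w_a", values=values)


def dispersal_weights(
    table: CommunityTable,
    distances: pd.DataFrame,
    distance_floor: float | None = None,
) -> AssemblyWeights:
    """Inverse-distance weighted relative abundances from putative sources.

    Zero pairwise distances (co-located samples) are floored at half the
    smallest nonzero distance (or ``distance_floor`` if given) before
    inversion, so same-site samples act as strong but finite sources.
    """
    if table.n_samples < 2:
        raise ValueError("dispersal weights need at least 2 samples")
    d = distances.to_numpy(dtype=float).copy()
    offdiag = ~np.eye(d.shape[0], dtype=bool)
    if distance_floor is None:
        nonzero = d[offdiag & (d > 0)]
        if nonzero.size == 0:
            raise ValueError("all pairwise distances are zero")
        distance_floor = 0.5 * nonzero.min()
    d[offdiag & (d < distance_floor)] = distance_floor

    inv = np.zeros_like(d)
    inv[offdiag] = 1.0 / d[offdiag]
    x = table.relative_abundance().to_numpy()
    w = (inv @ x) / inv.sum(axis=1, keepdims=True)
    values = pd.DataFrame(w, index=table.sample_ids, columns=table.taxon_ids)
    return AssemblyWeights(
        kind="w_d", values=values, provenance={"distance_floor_km": distance_floor}
    )


def environmental_weights(
    table: CommunityTable,
    env: pd.DataFrame,
    seed: int | None = None,
    n_folds: int = 5,
) -> AssemblyWeights:
    """Per-taxon occurrence probabilities from an RBF-kernel SVM classifier.

    For each taxon the presence/absence vector is regressed on the full
    environmental matrix (all soil principal components).  Probabilities are
    Platt-calibrated (logistic regression on the decision scores) and each
    sample's probability is predicted out-of-fold under 5-fold stratified
    cross-validation, so a flexible kernel cannot simply memorise the
    training presences -- in-sample probabilities from an interpolating
    classifier would make the environmental rule mimic any occupancy
    pattern whatsoever.

    Taxa present everywhere get probability 1; taxa absent everywhere get
    the floor 1e-6 (so occurrence draws stay defined); taxa whose minority
    class is rarer than the fold count fall back to their occupancy.
    """
    if table.n_samples < 2:
        raise ValueError("environmental weights need at least 2 samples")
    presence = table.presence().to_numpy()
    x = env.to_numpy(dtype=float)
    n, t = presence.shape
    probs = np.empty((n, t))
    params: dict[str, str] = {}
    for k in range(t):
        y = presence[:, k]
        occupancy = y.mean()
        minority = min(y.sum(), n - y.sum())
        if occupancy == 1.0:
            probs[:, k] = 1.0
            params[table.taxon_ids[k]] = "all-present"
        elif occupancy == 0.0:
            probs[:, k] = ZERO_WEIGHT_FLOOR
            params[table.taxon_ids[k]] = "all-absent"
        elif minority < n_folds:
            probs[:, k] = occupancy
            params[table.taxon_ids[k]] = "rare-occupancy"
        else:
            probs[:, k] = _oof_svc_probabilities(x, y, n_folds, seed)
            params[table.taxon_ids[k]] = "svc-rbf-oof"
    values = pd.DataFrame(probs, index=table.sample_ids, columns=table.taxon_ids)
    return AssemblyWeights(
        kind="w_e",
        values=values,
        provenance={
            "classifier": "SVC(kernel='rbf'), Platt-calibrated, out-of-fold",
            "n_folds": n_folds,
            "per_taxon": params,
        },
    )


def _oof_svc_probabilities(
    x: np.ndarray, y: np.ndarray, n_folds: int, seed: int | None
) -> np.ndarray:
    from sklearn.model_selection import StratifiedKFold

    out = np.empty(len(y), dtype=float)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for train, test in skf.split(x, y):
            clf = SVC(kernel="rbf", probability=True, random_state=seed)
            clf.fit(x[train], y[train])
            col = list(clf.classes_).index(True)
            out[test] = clf.predict_proba(x[test])[:, col]
    return out


def _dirichlet_alpha_floored(weights: np.ndarray) -> np.ndarray:
    """alpha = w/min(w) after flooring zero entries of the chosen set.

    w_e / w_d rows can contain exact zeros for chosen taxa; they are floored
    at 1e-6 x the largest chosen weight so the construction stays defined.
    """
    w = np.asarray(weights, dtype=float).copy()
    if w.max() <= 0:
        return np.ones_like(w)
    w[w <= 0] = ZERO_WEIGHT_FLOOR * w.max()
    return w / w.min()


def simulate_community(
    occurrence_weights: np.ndarray,
    abundance_weights: np.ndarray,
    richness: int,
    seed: int | np.random.Generator,
    fallback_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One simulated community for a single sample.

    ``richness`` taxa are drawn without replacement proportional to
    ``occurrence_weights``; if fewer taxa have positive weight, the
    remainder is drawn from ``fallback_weights`` (regional w_f) with a
    logged warning.  Abundances are Dirichlet(alpha = w*/min(w*)) over the
    chosen taxa.  Returns (chosen indices, relative abundances).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ow = np.asarray(occurrence_weights, dtype=float)
    t = len(ow)
    if not 1 <= richness <= t:
        raise ValueError(f"richness {richness} outside [1, {t}]")
    positive = ow > 0
    if positive.sum() >= richness:
        p = ow / ow.sum()
        chosen = rng.choice(t, size=richness, replace=False, p=p)
    else:
        if fallback_weights is None:
            raise ValueError(
                f"only {positive.sum()} taxa have positive occurrence weight "
                f"for requested richness {richness} and no fallback given"
            )
        logger.warning(
            "occurrence rule has %d positive-weight taxa < richness %d; "
            "drawing the remainder from regional frequencies",
            positive.sum(),
            richness,
        )
        chosen_pos = np.flatnonzero(positive)
        if chosen_pos.size:
            p = ow[chosen_pos] / ow[chosen_pos].sum()
            chosen_pos = rng.choice(chosen_pos, size=chosen_pos.size, replace=False, p=p)
        rest_pool = np.flatnonzero(~positive)
        fw = np.asarray(fallback_weights, dtype=float)[rest_pool]
        fw = np.where(fw > 0, fw, fw.max() * ZERO_WEIGHT_FLOOR + 1e-300)
        rest = rng.choice(
            rest_pool, size=richness - chosen_pos.size, replace=False, p=fw / fw.sum()
        )
        chosen = np.concatenate([chosen_pos, rest])
    if richness == 1:
        return chosen, np.array([1.0])
    alpha = _dirichlet_alpha_floored(np.asarray(abundance_weights, dtype=float)[chosen])
    return chosen, rng.dirichlet(alpha)


@dataclass
class ProcessScore:
    """Mean simulated-to-observed dissimilarities for one assembly process."""

    process: str
    occurrence_rule: str
    abundance_rule: str
    metric: str
    n_sims: int
    sample_scores: pd.Series  # per-sample mean dissimilarity
    mean_dissim: float


def _battery_sample_scores(
    occ_w: np.ndarray,
    ab_w: np.ndarray,
    obs_presence: np.ndarray,
    obs_rel: np.ndarray,
    richness: np.ndarray,
    w_f: np.ndarray,
    n_sims: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample mean Sorensen and Bray-Curtis over n_sims simulations.

    Vectorised over simulations with the Gumbel top-k trick; occurrence
    rules with too few positive weights fall back to regional frequencies
    for the remaining ranks (a large key offset keeps positive-weight taxa
    strictly ahead of fallback taxa).
    """
    n, t = occ_w.shape
    sor = np.empty(n)
    bc = np.empty(n)
    big = 1e9
    for i in range(n):
        w = occ_w[i]
        positive = w > 0
        logw = np.where(positive, np.log(np.where(positive, w, 1.0)), 0.0)
        fall = np.where(w_f > 0, np.log(np.where(w_f > 0, w_f, 1.0)), -big)
        base = np.where(positive, logw, fall - big)
        if positive.sum() < richness[i]:
            logger.warning(
                "sample %d: %d positive-weight taxa < richness %d; fallback to w_f",
                i,
                int(positive.sum()),
                int(richness[i]),
            )
        keys = base[None, :] + rng.gumbel(size=(n_sims, t))
        order = np.argsort(-keys, axis=1)
        mask = np.zeros((n_sims, t), dtype=bool)
        np.put_along_axis(mask, order[:, : richness[i]], True, axis=1)

        # abundance stage: Dirichlet(alpha) over the chosen set
        aw = np.where(mask, ab_w[i][None, :], 0.0)
        row_max = aw.max(axis=1, keepdims=True)
        aw = np.where(mask & (aw <= 0), ZERO_WEIGHT_FLOOR * row_max, aw)
        aw_min = np.where(mask, aw, np.inf).min(axis=1, keepdims=True)
        alpha = np.where(mask, aw / aw_min, 0.0)
        gam = rng.gamma(shape=np.where(mask, alpha, 1.0))
        gam = np.where(mask, gam, 0.0)
        sim_rel = gam / gam.sum(axis=1, keepdims=True)

        shared = (mask & obs_presence[i][None, :]).sum(axis=1)
        sor[i] = np.mean(1.0 - 2.0 * shared / (richness[i] + obs_presence[i].sum()))
        bc[i] = np.mean(0.5 * np.abs(sim_rel - obs_rel[i][None, :]).sum(axis=1))
    return sor, bc


def run_battery(
    table: CommunityTable,
    weights: dict[str, AssemblyWeights],
    n_sims: int,
    seed: int | np.random.Generator,
    processes: tuple[tuple[str, str], ...] = PROCESSES,
) -> list[ProcessScore]:
    """Score every assembly process by mean dissimilarity to the observed data.

    ``weights`` maps each rule kind (w_f, w_a, w_d, w_e) to its
    :class:`AssemblyWeights`.  Returns one :class:`ProcessScore` per process
    and metric (Sorensen and Bray-Curtis).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    missing = {k for pair in processes for k in pair} - set(weights)
    if missing:
        raise ValueError(f"missing weight families: {sorted(missing)}")
    obs_presence = table.presence().to_numpy()
    obs_rel = table.relative_abundance().to_numpy()
    richness = table.richness()
    w_f = weights["w_f"].values.to_numpy()[0]

    scores: list[ProcessScore] = []
    for occ_kind, ab_kind in processes:
        sor, bc = _battery_sample_scores(
            weights[occ_kind].values.to_numpy(),
            weights[ab_kind].values.to_numpy(),
            obs_presence,
            obs_rel,
            richness,
            w_f,
            n_sims,
            rng,
        )
        label = process_label(occ_kind, ab_kind)
        for metric, vals in (("sorensen", sor), ("bray_curtis", bc)):
            scores.append(
                ProcessScore(
                    process=label,
                    occurrence_rule=occ_kind,
                    abundance_rule=ab_kind,
                    metric=metric,
                    n_sims=n_sims,
                    sample_scores=pd.Series(vals, index=table.sample_ids),
                    mean_dissim=float(vals.mean()),
                )
            )
    return scores


def weight_correlation(w_d: AssemblyWeights, w_e: AssemblyWeights) -> float:
    """Pearson correlation of log dispersal vs log environmental weights.

    Computed over entries where both weights are positive (diagnostic for
    confounding between the two families).
    """
    a = w_d.values.to_numpy().ravel()
    b = w_e.values.to_numpy().ravel()
    ok = (a > 0) & (b > 0)
    if ok.sum() < 3:
        raise ValueError("too few jointly positive weights for a correlation")
    return float(np.corrcoef(np.log(a[ok]), np.log(b[ok]))[0, 1])


class MechanismBattery:
    """Model object for the seven-process assembly battery.

    Builds the four weight families from the community table, the pairwise
    distance matrix, and the environmental matrix (all soil PCs), then
    simulates and scores each process.

    Examples
    --------
    >>> model = MechanismBattery(table, distances, env_pcs)
    >>> res = model.fit(n_sims=1000, seed=0)
    >>> res.summary()          # process x metric mean dissimilarities
    >>> res.best_process("bray_curtis")
    """

    def __init__(
        self,
        table: CommunityTable,
        distances: pd.DataFrame,
        env: pd.DataFrame,
        distance_floor: float | None = None,
        classifier_seed: int | None = 0,
    ):
        self.table = table
        reg = regional_weights(table)
        self.weights = {
            "w_f": neutral_frequency_weights(table),
            "w_a": neutral_abundance_weights(table),
            "w_d": dispersal_weights(table, distances, distance_floor),
            "w_e": environmental_weights(table, env, seed=classifier_seed),
        }
        self.regional = reg

    def fit(self, n_sims: int = 1000, seed: int | None = None) -> "BatteryResults":
        scores = run_battery(self.table, self.weights, n_sims, np.random.default_rng(seed))
        return BatteryResults(model=self, scores=scores, n_sims=n_sims, seed=seed)


@dataclass
class BatteryResults:
    model: MechanismBattery
    scores: list[ProcessScore]
    n_sims: int
    seed: int | None

    def summary(self) -> pd.DataFrame:
        """Process x metric table of overall mean dissimilarities."""
        rows = {}
        for s in self.scores:
            rows.setdefault(s.process, {})[s.metric] = s.mean_dissim
        frame = pd.DataFrame(rows).T
        frame.index.name = "process"
        return frame.sort_values("bray_curtis")

    def sample_scores(self, metric: str) -> pd.DataFrame:
        """Per-sample mean dissimilarity, one column per process."""
        cols = {s.process: s.sample_scores for s in self.scores if s.metric == metric}
        return pd.DataFrame(cols)

    def best_process(self, metric: str = "bray_curtis") -> str:
        table = self.summary()
        return str(table[metric].idxmin())
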