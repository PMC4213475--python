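"""Node activation probabilities from expression via two-component mixtures.

Each expression feature (microarray probeset) is assumed to come from a
population mixing an *inactive* low-expression state and an *active*
high-expression state.  The mixture

    f(x) = pi0 * p0(x) + pi1 * p1(x)

is fitted per feature on a reference compendium by expectation-maximization,
with candidate component families normal-normal and gamma-normal (the
low-expression state is often heavy-tailed).  Given a new sample, Bayes'
theorem converts the observed expression x into a posterior probability of
the active state:

    P(Active | x) = pi1 * p1(x) / (pi0 * p0(x) + pi1 * p1(x))

Probe posteriors are aggregated to genes by the 90th percentile (robust
"highest credible evidence" summary), then to pathway nodes: a single-protein
node takes its gene's probability; an alternative-proteins node takes the
90th percentile over all probes of all member genes (any one protein
suffices); a complex node takes the minimum over member gene probabilities
(the least available member limits complex integrity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .pathway_io import NodeSpec, PathwayGraph

logger = logging.getLogger("sigcircuits.activation")

DEFAULT_FAMILIES: tuple[tuple[str, str], ...] = (("normal", "normal"), ("gamma", "normal"))
EM_MAX_ITER = 500
EM_TOL = 1e-8
MIN_FIT_VALUES = 30
DEGENERATE_PI = 1e-2
GENE_PERCENTILE = 90.0


class FitError(ValueError):
    """Mixture fitting cannot proceed (too few values, zero variance...)."""


@dataclass
class MixtureModel:
    """Fitted two-component mixture for one expression feature.

    Component 0 is the inactive (lower-mean) state, component 1 the active
    state.  ``params`` are (mean, sd) for normal and (shape, scale) for gamma.
    """

    feature_id: str
    family_inactive: str
    family_active: str
    params_inactive: tuple[float, float]
    params_active: tuple[float, float]
    pi0: float
    pi1: float
    log_likelihood: float = np.nan
    converged: bool = True
    degenerate: bool = False

    def __post_init__(self) -> None:
        if abs(self.pi0 + self.pi1 - 1.0) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")
        if self.mean_active + 1e-12 < self.mean_inactive:
            raise ValueError("active component must have the larger mean")

    @staticmethod
    def _mean(family: str, params: tuple[float, float]) -> float:
        if family == "normal":
            return params[0]
        if family == "gamma":
            return params[0] * params[1]
        raise ValueError(f"unknown family {family!r}")

    @property
    def mean_inactive(self) -> float:
        return self._mean(self.family_inactive, self.params_inactive)

    @property
    def mean_active(self) -> float:
        return self._mean(self.family_active, self.params_active)

    def _logpdf(self, which: int, x: np.ndarray) -> np.ndarray:
        family = self.family_inactive if which == 0 else self.family_active
        params = self.params_inactive if which == 0 else self.params_active
        if family == "normal":
            return stats.norm.logpdf(x, loc=params[0], scale=params[1])
        return stats.gamma.logpdf(x, a=params[0], scale=params[1])


def _kde_mode_init(values: np.ndarray) -> tuple[float, float]:
    """Initial component locations: the two highest peaks of a KDE of the data.

    Falls back to the 25th/75th percentiles when the density is unimodal.
    """
    lo, hi = values.min(), values.max()
    grid = np.linspace(lo, hi, 512)
    try:
        dens = stats.gaussian_kde(values)(grid)
    except np.linalg.LinAlgError:  # pragma: no cover - singular bandwidth
        return tuple(np.percentile(values, [25, 75]))  # type: ignore[return-value]
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.where(interior)[0] + 1
    if dens[0] > dens[1]:
        peaks = np.r_[0, peaks]
    if dens[-1] > dens[-2]:
        peaks = np.r_[peaks, len(grid) - 1]
    if len(peaks) < 2:
        q25, q75 = np.percentile(values, [25, 75])
        return float(q25), float(q75)
    top = peaks[np.argsort(dens[peaks])[::-1][:2]]
    m_lo, m_hi = sorted(grid[top])
    return float(m_lo), float(m_hi)


def _component_logpdf(family: str, params: tuple[float, float], x: np.ndarray) -> np.ndarray:
    if family == "normal":
        return stats.norm.logpdf(x, loc=params[0], scale=params[1])
    return stats.gamma.logpdf(x, a=params[0], scale=params[1])


def _m_step(family: str, x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted parameter update; gamma by moment matching on weighted moments."""
    wsum = w.sum()
    mean = float((w * x).sum() / wsum)
    var = float((w * (x - mean) ** 2).sum() / wsum)
    var = max(var, 1e-12)
    if family == "normal":
        return mean, float(np.sqrt(var))
    mean = max(mean, 1e-12)
    shape = mean * mean / var
    scale = var / mean
    return float(max(shape, 1e-6)), float(max(scale, 1e-12))


def _em_fit(
    values: np.ndarray,
    families: tuple[str, str],
    init_means: tuple[float, float],
    max_iter: int = EM_MAX_ITER,
    tol: float = EM_TOL,
) -> tuple[tuple[float, float], tuple[float, float], float, float, float, bool]:
    """Run EM for one family pair; returns (params0, params1, pi0, pi1, ll, converged)."""
    n = len(values)
    m_lo, m_hi = init_means
    sd0 = max(values.std() / 2.0, 1e-6)
    params = [
        _moment_params(families[0], m_lo, sd0),
        _moment_params(families[1], m_hi, sd0),
    ]
    pis = np.array([0.5, 0.5])
    prev_ll = -np.inf
    converged = False
    ll = -np.inf
    for _ in range(max_iter):
        logp = np.stack(
            [
                np.log(pis[0]) + _component_logpdf(families[0], params[0], values),
                np.log(pis[1]) + _component_logpdf(families[1], params[1], values),
            ]
        )
        norm = logsumexp(logp, axis=0)
        ll = float(norm.sum())
        resp = np.exp(logp - norm)
        pis = resp.sum(axis=1) / n
        pis = np.clip(pis, 1e-10, 1.0)
        pis = pis / pis.sum()
        params = [
            _m_step(families[0], values, resp[0]),
            _m_step(families[1], values, resp[1]),
        ]
        if prev_ll > -np.inf and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1e-12):
            converged = True
            break
        prev_ll = ll
    return params[0], params[1], float(pis[0]), float(pis[1]), ll, converged


def _moment_params(family: str, mean: float, sd: float) -> tuple[float, float]:
    if family == "normal":
        return float(mean), float(sd)
    mean = max(mean, 1e-6)
    var = max(sd * sd, 1e-12)
    return float(mean * mean / var), float(var / mean)


def fit_mixture(
    values: Sequence[float] | np.ndarray,
    families: Iterable[tuple[str, str]] = DEFAULT_FAMILIES,
    feature_id: str = "",
    max_iter: int = EM_MAX_ITER,
    tol: float = EM_TOL,
) -> MixtureModel:
    """EM-fit a two-component mixture on reference expression values.

    Candidate (inactive, active) family pairs are fitted independently and the
    best by log-likelihood wins (BIC breaks ties; both candidates here have
    equal parameter counts, so the tie-break reduces to candidate order).
    The lower-mean component is labeled inactive.  A near-empty component
    (min proportion < 1%) flags the fit degenerate: the feature behaves as a
    single population.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < MIN_FIT_VALUES:
        raise FitError(f"need >= {MIN_FIT_VALUES} finite values, got {len(x)}")
    if x.std() <= 0:
        raise FitError("zero-variance input")
    init = _kde_mode_init(x)
    best = None
    any_converged = False
    for pair in families:
        if "gamma" in pair and x.min() <= 0:
            logger.debug("%s: skipping %s (non-positive values)", feature_id, pair)
            continue
        p0, p1, pi0, pi1, ll, conv = _em_fit(x, pair, init, max_iter=max_iter, tol=tol)
        any_converged = any_converged or conv
        if best is None or ll > best[-2]:
            best = (pair, p0, p1, pi0, pi1, ll, conv)
    if best is None:
        raise FitError("no admissible family pair for this feature")
    pair, p0, p1, pi0, pi1, ll, conv = best
    if not any_converged:
        # fallback: single-family refit (one normal population, split evenly)
        logger.warning("%s: EM did not converge; falling back to a single normal", feature_id)
        mu, sd = float(x.mean()), float(max(x.std(), 1e-6))
        return MixtureModel(
            feature_id=feature_id,
            family_inactive="normal",
            family_active="normal",
            params_inactive=(mu, sd),
            params_active=(mu, sd),
            pi0=0.5,
            pi1=0.5,
            log_likelihood=float(stats.norm.logpdf(x, mu, sd).sum()),
            converged=False,
            degenerate=True,
        )
    # order components: inactive = lower mean
    mean0 = MixtureModel._mean(pair[0], p0)
    mean1 = MixtureModel._mean(pair[1], p1)
    if mean0 > mean1:
        pair = (pair[1], pair[0])
        p0, p1 = p1, p0
        pi0, pi1 = pi1, pi0
    # degenerate: an essentially empty component, or two components so close
    # that the data behave as a single population
    spread = float(np.std(x))
    separation = (MixtureModel._mean(pair[1], p1) - MixtureModel._mean(pair[0], p0)) / max(
        spread, 1e-12
    )
    degenerate = min(pi0, pi1) < DEGENERATE_PI or separation < 1.0
    if degenerate:
        logger.info(
            "%s: degenerate mixture (pi=%.4f/%.4f, separation=%.2f sd)",
            feature_id, pi0, pi1, separation,
        )
    return MixtureModel(
        feature_id=feature_id,
        family_inactive=pair[0],
        family_active=pair[1],
        params_inactive=p0,
        params_active=p1,
        pi0=pi0,
        pi1=pi1,
        log_likelihood=ll,
        converged=conv,
        degenerate=degenerate,
    )


def posterior_active(x: float | np.ndarray, model: MixtureModel) -> float | np.ndarray:
    """P(Active | x) = pi1*p1(x) / (pi0*p0(x) + pi1*p1(x)), clipped to [0, 1].

    Deep in the tails both densities can underflow; there the posterior is
    resolved by which component mean x is beyond (1 above the active mean,
    else 0).
    """
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    with np.errstate(divide="ignore"):
        log_num = np.log(model.pi1) + model._logpdf(1, arr)
        log_p0 = np.log(model.pi0) + model._logpdf(0, arr)
    log_den = np.logaddexp(log_p0, log_num)
    with np.errstate(invalid="ignore"):
        post = np.exp(log_num - log_den)
    underflow = ~np.isfinite(log_den)
    if underflow.any():
        logger.debug("posterior underflow at %d value(s); resolving by tail side", underflow.sum())
        post = np.where(underflow, (arr > model.mean_active).astype(float), post)
    post = np.clip(post, 0.0, 1.0)
    return float(post[0]) if scalar else post


def aggregate_percentile(
    probabilities: Sequence[float] | np.ndarray, q: float = GENE_PERCENTILE
) -> float | np.ndarray:
    """q-th percentile with linear interpolation; rows aggregate if 2-D (rows x samples)."""
    arr = np.asarray(probabilities, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty probability vector")
    if arr.ndim == 1:
        return float(np.percentile(arr, q))
    return np.percentile(arr, q, axis=0)


def drop_multimapping_probes(probe_map: pd.DataFrame) -> pd.DataFrame:
    """Remove probes that map to more than one distinct gene.

    ``probe_map`` has columns ``probe_id`` and ``gene_id``.  Probes mapping
    multiple genes carry ambiguous signal and are discarded.
    """
    counts = probe_map.groupby("probe_id")["gene_id"].nunique()
    multi = set(counts.index[counts > 1])
    if multi:
        logger.info("discarding %d multi-mapping probe(s)", len(multi))
    kept = probe_map[~probe_map["probe_id"].isin(multi)].drop_duplicates()
    if kept.empty:
        raise ValueError("no probes left after discarding multi-mapping probes")
    return kept.reset_index(drop=True)


# ---------------------------------------------------------------------------
# matrix-level pipeline
# ---------------------------------------------------------------------------

def fit_mixtures(
    compendium: pd.DataFrame,
    families: Iterable[tuple[str, str]] = DEFAULT_FAMILIES,
    max_iter: int = EM_MAX_ITER,
) -> dict[str, MixtureModel]:
    """Fit a mixture per feature (row) of the reference compendium."""
    models: dict[str, MixtureModel] = {}
    for feature, row in compendium.iterrows():
        try:
            models[str(feature)] = fit_mixture(
                row.to_numpy(), families=families, feature_id=str(feature), max_iter=max_iter
            )
        except FitError as exc:
            logger.warning("feature %s not fitted: %s", feature, exc)
    if not models:
        raise FitError("no feature could be fitted on the compendium")
    return models


def mixtures_table(models: Mapping[str, MixtureModel]) -> pd.DataFrame:
    rows = []
    for m in models.values():
        rows.append(
            {
                "feature_id": m.feature_id,
                "family_inactive": m.family_inactive,
                "family_active": m.family_active,
                "param1_inactive": m.params_inactive[0],
                "param2_inactive": m.params_inactive[1],
                "param1_active": m.params_active[0],
                "param2_active": m.params_active[1],
                "pi0": m.pi0,
                "pi1": m.pi1,
                "log_likelihood": m.log_likelihood,
                "converged": m.converged,
                "degenerate": m.degenerate,
            }
        )
    return pd.DataFrame(rows)


def probe_posteriors(
    expression: pd.DataFrame, models: Mapping[str, MixtureModel]
) -> pd.DataFrame:
    """Per-probe, per-sample activation posteriors for a study matrix."""
    common = [p for p in expression.index if str(p) in models]
    missing = len(expression) - len(common)
    if missing:
        logger.info("%d expression feature(s) have no fitted mixture; dropped", missing)
    if not common:
        raise ValueError("no overlap between expression features and fitted mixtures")
    out = np.empty((len(common), expression.shape[1]))
    for i, probe in enumerate(common):
        out[i] = posterior_active(expression.loc[probe].to_numpy(), models[str(probe)])
    return pd.DataFrame(out, index=pd.Index(common, name=expression.index.name), columns=expression.columns)


def gene_probabilities(
    probe_probs: pd.DataFrame, probe_map: pd.DataFrame, q: float = GENE_PERCENTILE
) -> pd.DataFrame:
    """Aggregate probe posteriors to genes via the q-th percentile per sample."""
    pm = drop_multimapping_probes(probe_map)
    pm = pm[pm["probe_id"].isin(probe_probs.index)]
    if pm.empty:
        raise ValueError("probe map shares no probes with the posterior matrix")
    rows = {}
    for gene, grp in pm.groupby("gene_id"):
        block = probe_probs.loc[grp["probe_id"]].to_numpy()
        rows[gene] = np.percentile(block, q, axis=0)
    genes = sorted(rows)
    return pd.DataFrame(
        np.vstack([rows[g] for g in genes]),
        index=pd.Index(genes, name="gene_id"),
        columns=probe_probs.columns,
    )


def node_probability(
    node: NodeSpec,
    gene_probs: Mapping[str, float | np.ndarray],
    probe_probs: pd.DataFrame | None = None,
    probe_map: pd.DataFrame | None = None,
    q: float = GENE_PERCENTILE,
) -> float | np.ndarray | None:
    """Activation probability of one pathway node.

    single: the member gene's probability.  alternatives: q-th percentile
    over all probes of all member genes when probe-level data is available
    (else over member gene probabilities).  complex: minimum over member
    gene probabilities.  Returns None when every member gene is missing
    (non-informative node); partially missing members are skipped with a log.
    """
    present = [g for g in node.genes if g in gene_probs]
    if not present:
        logger.info("node %s: no member gene measured; non-informative", node.node_id)
        return None
    if len(present) < len(node.genes):
        logger.info(
            "node %s: %d/%d member gene(s) missing from data",
            node.node_id, len(node.genes) - len(present), len(node.genes),
        )
    if node.kind == "single":
        return gene_probs[present[0]]
    if node.kind == "complex":
        stacked = np.stack([np.asarray(gene_probs[g], dtype=float) for g in present])
        out = stacked.min(axis=0)
        return float(out) if out.ndim == 0 else out
    # alternatives: pool probes of all member genes when available
    if probe_probs is not None and probe_map is not None:
        probes = probe_map[probe_map["gene_id"].isin(present)]["probe_id"]
        probes = [p for p in probes if p in probe_probs.index]
        if probes:
            return aggregate_percentile(probe_probs.loc[probes].to_numpy(), q)
    stacked = np.stack([np.asarray(gene_probs[g], dtype=float) for g in present])
    return aggregate_percentile(stacked, q)


def node_probabilities(
    graph: PathwayGraph,
    gene_probs: pd.DataFrame,
    probe_probs: pd.DataFrame | None = None,
    probe_map: pd.DataFrame | None = None,
    q: float = GENE_PERCENTILE,
) -> pd.DataFrame:
    """Node x sample activation matrix for one pathway (missing nodes omitted)."""
    gene_map = {g: gene_probs.loc[g].to_numpy() for g in gene_probs.index}
    rows = {}
    for node_id, spec in graph.nodes.items():
        p = node_probability(spec, gene_map, probe_probs, probe_map, q=q)
        if p is not None:
            rows[node_id] = np.broadcast_to(np.asarray(p, dtype=float), (gene_probs.shape[1],))
    if not rows:
        raise ValueError(f"pathway {graph.pathway_id}: no node has measured genes")
    return pd.DataFrame(
        np.vstack(list(rows.values())),
        index=pd.Index(list(rows), name="node_id"),
        columns=gene_probs.columns,
    )


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str) -> pd.DataFrame:
    """Features x samples matrix with a header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_probe_map_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_id", "gene_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"probe map must have columns {sorted(required)}")
    return df[["probe_id", "gene_id"]]
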