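"""QTL meta-analysis: mixture clustering of projected QTL into meta-QTL.

The projected QTL positions on one chromosome are modelled as a
one-dimensional Gaussian mixture with *known, observation-specific*
variances: QTL i contributes

    p(x_i) = sum_k pi_k * Normal(x_i; mu_k, s_i^2),

where ``s_i`` is the standard deviation implied by the QTL's own projected
95% CI (``s_i = CI width / 3.92``) and ``mu_k`` are the unknown meta-QTL
(MQTL) positions.  Because the variances are fixed, only the K component
means and K-1 free weights are estimated (``p = 2K - 1`` parameters), and
the M-step mean is the responsibility- and precision-weighted average of the
member positions.

The analysis is the classical two-step procedure: first the number of
components K is chosen by fitting K = 1..K_max and taking the *most
prevalent* minimizer across five information criteria (AIC, AICc, AIC3, BIC
and AWE, the latter on the classification likelihood); then MQTL positions,
95% CIs and averaged member LOD/PVE are derived from the selected fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .projection import ProjectedQTL
from .qtl_data import CI95_Z

__all__ = [
    "MixtureFit",
    "MQTL",
    "MetaConfig",
    "em_fit",
    "information_criteria",
    "criteria_table",
    "select_k",
    "summarize_mqtl",
    "run_chromosome",
    "mqtl_to_frame",
]

CRITERIA = ("AIC", "AICc", "AIC3", "BIC", "AWE")

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class MixtureFit:
    """Converged EM fit of a K-component mixture on one chromosome."""

    K: int
    means: np.ndarray          # (K,) component positions, cM
    weights: np.ndarray        # (K,) mixing proportions
    resp: np.ndarray           # (n, K) responsibilities
    loglik: float
    converged: bool
    n_iter: int
    seed: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n(self) -> int:
        return self.resp.shape[0]

    @property
    def n_params(self) -> int:
        return 2 * self.K - 1

    def hard_assignment(self) -> np.ndarray:
        return np.argmax(self.resp, axis=1)


@dataclass
class MQTL:
    """One meta-QTL: consensus cluster of initial QTL on one chromosome."""

    name: str
    chromosome: str
    position: float
    ci_lo: float
    ci_hi: float
    members: list[ProjectedQTL]
    mean_lod: float
    mean_pve: float

    @property
    def n_qtl(self) -> int:
        return len(self.members)

    @property
    def n_studies(self) -> int:
        return len({m.record.study_id for m in self.members})

    @property
    def ci_width(self) -> float:
        return self.ci_hi - self.ci_lo

    @property
    def trait_classes(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.members:
            counts[m.record.trait_class] = counts.get(m.record.trait_class, 0) + 1
        return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


@dataclass
class MetaConfig:
    """Tunables of the mixture meta-analysis."""

    k_max: int = 20
    restarts: int = 10
    max_iter: int = 500
    tol: float = 1e-8
    seed: int = 0
    membership: Literal["soft", "hard"] = "soft"
    min_sd: float = 1e-3  # cM floor on observation sd (degenerate zero-width CIs)


def _log_density(x: np.ndarray, sd: np.ndarray, means: np.ndarray) -> np.ndarray:
    """(n, K) matrix of log Normal(x_i; mu_k, s_i^2)."""
    z = (x[:, None] - means[None, :]) / sd[:, None]
    return -0.5 * (z**2) - np.log(sd)[:, None] - 0.5 * _LOG_2PI


def _em_batch(
    x: np.ndarray,
    sd: np.ndarray,
    means0: np.ndarray,
    max_iter: int,
    tol: float,
):
    """Run R EM chains in parallel from a (R, K) array of initial means.

    Returns per-chain means, weights, responsibilities, log-likelihoods,
    convergence flags, iteration counts and log-likelihood traces.
    """
    R, K = means0.shape
    n = len(x)
    means = means0.astype(float).copy()
    weights = np.full((R, K), 1.0 / K)
    prec = 1.0 / sd**2
    loglik = np.full(R, -np.inf)
    resp = np.full((R, n, K), 1.0 / K)
    n_iter = np.zeros(R, dtype=int)
    converged = np.zeros(R, dtype=bool)
    traces: list[list[float]] = [[] for _ in range(R)]
    log_base = -np.log(sd)[None, :, None] - 0.5 * _LOG_2PI
    active = np.ones(R, dtype=bool)
    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        z = (x[None, :, None] - means[idx, None, :]) / sd[None, :, None]
        logp = -0.5 * z**2 + log_base + np.log(weights[idx])[:, None, :]
        m = logp.max(axis=2, keepdims=True)
        lse = m[..., 0] + np.log(np.exp(logp - m).sum(axis=2))
        new_ll = lse.sum(axis=1)
        r = np.exp(logp - lse[..., None])
        resp[idx] = r
        for j, i in enumerate(idx):
            traces[i].append(float(new_ll[j]))
        done = (new_ll - loglik[idx] < tol * np.maximum(1.0, np.abs(new_ll))) & (
            n_iter[idx] > 0
        )
        loglik[idx] = new_ll
        n_iter[idx] = it
        converged[idx[done]] = True
        active[idx[done]] = False
        rem = idx[~done]
        if rem.size == 0:
            break
        # M-step: precision-weighted means, average responsibilities
        rr = r[~done]
        wk = rr * prec[None, :, None]
        denom = wk.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            means[rem] = np.where(
                denom > 0, (wk * x[None, :, None]).sum(axis=1) / denom, means[rem]
            )
        w = np.clip(rr.mean(axis=1), 1e-12, None)
        weights[rem] = w / w.sum(axis=1, keepdims=True)
    return means, weights, resp, loglik, converged, n_iter, traces


def _em_single(
    x: np.ndarray,
    sd: np.ndarray,
    means0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, int, np.ndarray]:
    """One EM chain (batch of size 1); kept as the reference entry point."""
    means, weights, resp, ll, conv, its, traces = _em_batch(
        np.asarray(x, float), np.asarray(sd, float), means0[None, :], max_iter, tol
    )
    return (
        means[0],
        weights[0],
        resp[0],
        float(ll[0]),
        bool(conv[0]),
        int(its[0]),
        np.asarray(traces[0]),
    )


def em_fit(
    positions: Sequence[float],
    sds: Sequence[float],
    K: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    restarts: int = 10,
) -> MixtureFit:
    """Fit the K-component heteroscedastic mixture, best of ``restarts``.

    The first restart is initialized from quantile-spaced means (so K=1 and
    well-separated problems are deterministic regardless of seed); later
    restarts start from K distinct data points sampled at random, which
    explores cluster assignments far from the quantile grid.
    """
    x = np.asarray(positions, dtype=float)
    s = np.asarray(sds, dtype=float)
    if x.ndim != 1 or x.shape != s.shape:
        raise ValueError("positions and sds must be 1-D and the same length")
    if not (np.isfinite(x).all() and np.isfinite(s).all()):
        raise ValueError("non-finite positions or sds")
    if np.any(s <= 0):
        raise ValueError("all sds must be > 0")
    n = len(x)
    if not 1 <= K <= n:
        raise ValueError(f"need 1 <= K <= n, got K={K}, n={n}")

    rng = np.random.default_rng(seed)
    R = max(restarts, 1)
    means0 = np.empty((R, K))
    means0[0] = np.quantile(x, (np.arange(K) + 0.5) / K)
    for r in range(1, R):
        means0[r] = rng.choice(x, size=K, replace=False)
    means, weights, resp, ll, conv, its, traces = _em_batch(
        x, s, means0, max_iter, tol
    )
    r_best = int(np.argmax(ll))
    best = MixtureFit(
        K,
        means[r_best],
        weights[r_best],
        resp[r_best],
        float(ll[r_best]),
        bool(conv[r_best]),
        int(its[r_best]),
        seed,
        np.asarray(traces[r_best]),
    )
    order = np.argsort(best.means, kind="stable")
    best.means = best.means[order]
    best.weights = best.weights[order]
    best.resp = best.resp[:, order]
    return best


def classification_loglik(fit: MixtureFit, x: np.ndarray, sd: np.ndarray) -> float:
    """Log-likelihood under hard assignments z_i = argmax_k r_ik."""
    z = fit.hard_assignment()
    logp = _log_density(x, sd, fit.means) + np.log(np.clip(fit.weights, 1e-300, None))
    return float(logp[np.arange(len(x)), z].sum())


def information_criteria(
    fit: MixtureFit, x: np.ndarray, sd: np.ndarray
) -> dict[str, float]:
    """AIC, AICc, AIC3, BIC and AWE for one fit (p = 2K - 1 parameters).

    AICc is undefined (NaN) when n <= p + 1.  AWE uses the classification
    log-likelihood: ``AWE = -2 lnL_c + 2 p (3/2 + ln n)``.
    """
    n = fit.n
    p = fit.n_params
    m2ll = -2.0 * fit.loglik
    aic = m2ll + 2.0 * p
    aicc = aic + 2.0 * p * (p + 1) / (n - p - 1) if n > p + 1 else math.nan
    aic3 = m2ll + 3.0 * p
    bic = m2ll + p * math.log(n)
    llc = classification_loglik(fit, x, sd)
    awe = -2.0 * llc + 2.0 * p * (1.5 + math.log(n))
    return {"AIC": aic, "AICc": aicc, "AIC3": aic3, "BIC": bic, "AWE": awe}


def criteria_table(
    x: np.ndarray, sd: np.ndarray, config: MetaConfig
) -> tuple[pd.DataFrame, dict[int, MixtureFit]]:
    """Fit K = 1..min(k_max, n) and tabulate the five criteria per K."""
    n = len(x)
    fits: dict[int, MixtureFit] = {}
    rows = []
    for K in range(1, min(config.k_max, n) + 1):
        fit = em_fit(
            x,
            sd,
            K,
            seed=config.seed + K,
            max_iter=config.max_iter,
            tol=config.tol,
            restarts=config.restarts,
        )
        fits[K] = fit
        rows.append({"K": K, **information_criteria(fit, x, sd)})
    table = pd.DataFrame(rows).set_index("K")
    return table, fits


def select_k(table: pd.DataFrame) -> tuple[int, dict[str, int]]:
    """Choose K by majority vote of the criteria's minimizers.

    Each criterion votes the K minimizing it (criteria undefined for every K,
    e.g. AICc on tiny n, abstain); the modal vote wins, ties broken toward
    the smallest K (parsimony).
    """
    votes: dict[str, int] = {}
    for crit in CRITERIA:
        col = table[crit]
        if col.notna().any():
            votes[crit] = int(col.idxmin())
    if not votes:
        raise ValueError("no criterion defined for any K")
    tally: dict[int, int] = {}
    for k in votes.values():
        tally[k] = tally.get(k, 0) + 1
    best = min(tally, key=lambda k: (-tally[k], k))
    return best, votes


def summarize_mqtl(
    fit: MixtureFit,
    projected: Sequence[ProjectedQTL],
    chromosome: str,
    membership: Literal["soft", "hard"] = "soft",
    min_sd: float = 1e-3,
) -> list[MQTL]:
    """Derive MQTL records from a fitted mixture.

    Membership is by hard assignment; the MQTL position is the component
    mean and its 95% CI comes from the precision-pooled variance
    ``Var(mu_k) = 1 / sum_i w_ik / s_i^2`` with ``w_ik`` the responsibilities
    (``membership="soft"``) or the 0/1 hard assignments (``"hard"``).
    Components with no hard members are skipped (callers refit with K-1).
    Names are ``MQTL{chrom}-{rank}`` with rank by position.
    """
    x = np.array([p.proj_position for p in projected])
    sd = np.maximum([p.sd for p in projected], min_sd)
    z = fit.hard_assignment()
    prec = 1.0 / np.asarray(sd) ** 2
    out: list[MQTL] = []
    for k in np.argsort(fit.means, kind="stable"):
        members = [p for i, p in enumerate(projected) if z[i] == k]
        if not members:
            continue
        if membership == "soft":
            pooled_prec = float((fit.resp[:, k] * prec).sum())
        else:
            pooled_prec = float(prec[z == k].sum())
        half = CI95_Z / math.sqrt(pooled_prec)
        lods = [m.record.lod for m in members if m.record.lod is not None]
        pves = [m.record.pve for m in members if m.record.pve is not None]
        out.append(
            MQTL(
                name="",
                chromosome=chromosome,
                position=float(fit.means[k]),
                ci_lo=float(fit.means[k] - half),
                ci_hi=float(fit.means[k] + half),
                members=members,
                mean_lod=float(np.mean(lods)) if lods else math.nan,
                mean_pve=float(np.mean(pves)) if pves else math.nan,
            )
        )
    out.sort(key=lambda m: m.position)
    for i, m in enumerate(out, start=1):
        m.name = f"MQTL{chromosome}-{i}"
    return out


@dataclass
class ChromosomeResult:
    """Meta-analysis output for one chromosome."""

    chromosome: str
    mqtls: list[MQTL]
    unassigned: list[ProjectedQTL]  # members whose CI misses their MQTL CI
    k_selected: int
    votes: dict[str, int]
    criteria: pd.DataFrame
    refitted: bool = False  # true when empty components forced a smaller K


def run_chromosome(
    projected: Sequence[ProjectedQTL], config: MetaConfig
) -> ChromosomeResult:
    """Full two-step meta-analysis of one chromosome.

    Fits K = 1..min(k_max, n), selects K by modal vote, summarizes MQTL,
    and flags members whose projected CI does not overlap their MQTL's CI as
    *unintegrated* (returned separately, excluded from membership).  If the
    selected fit leaves hard-empty components, K is reduced until none are
    empty.
    """
    usable = [p for p in projected if p.projectable]
    if not usable:
        raise ValueError("no projectable QTL on this chromosome")
    chrom = usable[0].chromosome
    x = np.array([p.proj_position for p in usable])
    sd = np.maximum([p.sd for p in usable], config.min_sd)

    table, fits = criteria_table(x, sd, config)
    k_star, votes = select_k(table)

    refitted = False
    fit = fits[k_star]
    while k_star > 1 and len(np.unique(fit.hard_assignment())) < fit.K:
        k_star -= 1
        fit = fits[k_star]
        refitted = True

    mqtls = summarize_mqtl(fit, usable, chrom, config.membership, config.min_sd)

    unassigned: list[ProjectedQTL] = []
    for m in mqtls:
        kept = []
        for p in m.members:
            if p.proj_ci_hi < m.ci_lo or p.proj_ci_lo > m.ci_hi:
                unassigned.append(p)
            else:
                kept.append(p)
        m.members = kept
        lods = [p.record.lod for p in kept if p.record.lod is not None]
        pves = [p.record.pve for p in kept if p.record.pve is not None]
        m.mean_lod = float(np.mean(lods)) if lods else math.nan
        m.mean_pve = float(np.mean(pves)) if pves else math.nan
    mqtls = [m for m in mqtls if m.members]
    for i, m in enumerate(sorted(mqtls, key=lambda m: m.position), start=1):
        m.name = f"MQTL{chrom}-{i}"

    return ChromosomeResult(chrom, mqtls, unassigned, k_star, votes, table, refitted)


def mqtl_to_frame(mqtls: Sequence[MQTL]) -> pd.DataFrame:
    """MQTL table in the standard reporting schema."""
    rows = []
    for m in mqtls:
        rows.append(
            {
                "name": m.name,
                "chrom": m.chromosome,
                "pos_cM": m.position,
                "ci_lo": m.ci_lo,
                "ci_hi": m.ci_hi,
                "n_qtl": m.n_qtl,
                "n_studies": m.n_studies,
                "traits": ";".join(f"{k}:{v}" for k, v in m.trait_classes.items()),
                "mean_lod": m.mean_lod,
                "mean_pve": m.mean_pve,
                "member_qtl_ids": ";".join(p.record.qtl_id for p in m.members),
            }
        )
    return pd.DataFrame(rows)
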