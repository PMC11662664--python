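"""IP-versus-Input differential interaction analysis and "Special" RNA sets.

Per-RNA interaction counts from replicated IP and Input libraries are
TMM-normalized, a common NB dispersion is estimated by conditional maximum
likelihood on library-size-adjusted pseudo-counts, and each RNA is tested for
a condition difference with the NB exact test (two-sided, doubled smaller
tail). RNAs are called enriched at adjusted P <= 0.1 and |log2FC| >= 0.5,
and a condition's "Special" set is the union of its enriched RNAs and the
RNAs captured only in that condition.

The TMM + exact-test core is implemented here directly so the pipeline stays
self-contained; it follows the standard weighted doubly-trimmed M-value and
conditional NB formulation used for count libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .significance import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_ADJP = 0.1
DEFAULT_LFC = 0.5
FALLBACK_DISPERSION = 0.1  # used when no condition has replication


@dataclass
class SpecialSets:
    """Per-condition unique / enriched / special RNA memberships."""

    unique: dict[str, set[str]]
    enriched: dict[str, set[str]]
    special: dict[str, set[str]] = field(init=False)

    def __post_init__(self) -> None:
        self.special = {cond: self.unique[cond] | self.enriched[cond]
                        for cond in self.unique}


def tmm_factors(counts: np.ndarray | pd.DataFrame, ref: int | None = None,
                trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    ``counts`` is genes x samples. The reference sample, unless given, is the
    one whose upper-quartile count proportion is closest to the mean across
    samples. M-values (log2 relative proportion changes vs the reference) are
    doubly trimmed (30% on M, 5% on A) and averaged with inverse asymptotic
    variance weights.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a genes x samples matrix with >= 2 samples")
    lib = x.sum(axis=0)
    if np.all(lib == 0):
        raise ValueError("all library sizes are zero")
    if np.any(lib == 0):
        logger.warning("empty librar%s given factor 1",
                       "ies" if (lib == 0).sum() > 1 else "y")
    nonzero = np.nonzero(lib)[0]
    if ref is None:
        f75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in nonzero])
        ref = int(nonzero[np.argmin(np.abs(f75 - f75.mean()))])
    factors = np.ones(x.shape[1])
    for j in nonzero:
        if j == ref:
            continue
        factors[j] = _tmm_pair(x[:, j], x[:, ref], lib[j], lib[ref],
                               trim_m, trim_a)
    return factors / np.exp(np.mean(np.log(factors)))


def _tmm_pair(obs: np.ndarray, refc: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    both = (obs > 0) & (refc > 0)
    if not both.any():
        logger.warning("no genes shared with the TMM reference; factor set to 1")
        return 1.0
    o, r = obs[both], refc[both]
    log_r = np.log2((o / n_obs) / (r / n_ref))          # M
    abs_e = (np.log2(o / n_obs) + np.log2(r / n_ref)) / 2  # A
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(log_r)
    rank_a = stats.rankdata(abs_e)
    keep = ((rank_m >= lo_l) & (rank_m <= hi_l) &
            (rank_a >= lo_s) & (rank_a <= hi_s))
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f) if np.isfinite(f) else 1.0


def _pseudo_counts(counts: np.ndarray, factors: np.ndarray,
                   lib_sizes: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Scale libraries to a common effective size (geometric mean)."""
    lib = counts.sum(axis=0) if lib_sizes is None else np.asarray(lib_sizes, float)
    eff = lib * factors
    pos = eff > 0
    common = float(np.exp(np.mean(np.log(eff[pos]))))
    scale = np.where(pos, common / np.where(pos, eff, 1.0), 1.0)
    return counts * scale, common


def _group_cond_loglik(y: np.ndarray, r: float) -> float:
    """NB log-likelihood of one gene's counts in one group, conditional on
    their total (equal library sizes assumed; phi-independent terms dropped)."""
    n = y.size
    z = y.sum()
    return float(special.gammaln(y + r).sum() - n * special.gammaln(r)
                 + special.gammaln(n * r) - special.gammaln(z + n * r))


def estimate_dispersion(counts: np.ndarray | pd.DataFrame, groups,
                        factors: np.ndarray | None = None,
                        lib_sizes: np.ndarray | None = None) -> tuple[float, str]:
    """Common NB dispersion by conditional ML on pseudo-counts.

    Libraries are first equalized (TMM-scaled to the geometric-mean effective
    size); within each condition with >= 2 replicates, each gene contributes
    its conditional likelihood given the gene-group total. Returns
    ``(phi, method)`` where method is ``cml`` or ``fallback`` (no replication
    anywhere: a fixed, configurable dispersion of 0.1 is reported).
    """
    x = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    if factors is None:
        factors = tmm_factors(x) if x.shape[1] >= 2 else np.ones(x.shape[1])
    pseudo, _ = _pseudo_counts(x, factors, lib_sizes)
    rep_groups = [g for g in np.unique(groups) if (groups == g).sum() >= 2]
    if not rep_groups:
        logger.warning("no replication in any condition; using fallback "
                       "dispersion %.3g", FALLBACK_DISPERSION)
        return FALLBACK_DISPERSION, "fallback"

    blocks = [pseudo[:, groups == g] for g in rep_groups]

    def neg_cond_ll(log_phi: float) -> float:
        r = 1.0 / np.exp(log_phi)
        total = 0.0
        for block in blocks:
            for gi in range(block.shape[0]):
                y = block[gi]
                if y.sum() > 0:
                    total += _group_cond_loglik(y, r)
        return -total

    res = optimize.minimize_scalar(neg_cond_ll, bounds=(np.log(1e-8), np.log(5.0)),
                                   method="bounded",
                                   options={"xatol": 1e-6})
    return float(np.exp(res.x)), "cml"


def _exact_nb_pvalue(za: float, zb: float, na: int, nb: int, r: float) -> float:
    """Two-sided exact NB test p-value, conditional on the total count.

    Group sums of iid NB(r, p) variables are NB(n*r, p), so conditional on
    z = za + zb the group-A sum follows a negative hypergeometric-type law
    that is free of p. The two-sided p doubles the smaller tail (capped at 1).
    """
    z = int(round(za + zb))
    if z == 0:
        return 1.0
    ra, rb = na * r, nb * r
    k = np.arange(z + 1)
    logw = (special.gammaln(k + ra) - special.gammaln(k + 1)
            + special.gammaln(z - k + rb) - special.gammaln(z - k + 1))
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    ka = int(round(za))
    lower = w[:ka + 1].sum()
    upper = w[ka:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def nb_test(counts: np.ndarray | pd.DataFrame, groups,
            factors: np.ndarray | None = None,
            phi: float | None = None,
            prior_count: float = 0.5,
            lib_sizes: np.ndarray | None = None) -> pd.DataFrame:
    """Per-gene two-group NB exact test on TMM-equalized pseudo-counts.

    Returns a frame with ``log2fc`` (second group over first, prior count 0.5
    on normalized means), two-sided ``p`` and BH ``adj_p``. All-zero genes get
    p = 1 and log2fc = 0.
    """
    x = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {levels}")
    if factors is None:
        factors = tmm_factors(x)
    if phi is None:
        phi, _ = estimate_dispersion(x, groups, factors, lib_sizes)
    pseudo, _ = _pseudo_counts(x, factors, lib_sizes)
    a_mask, b_mask = groups == levels[0], groups == levels[1]
    na, nb_ = int(a_mask.sum()), int(b_mask.sum())
    r = 1.0 / max(phi, 1e-8)
    pvals = np.ones(x.shape[0])
    lfc = np.zeros(x.shape[0])
    for gi in range(x.shape[0]):
        ya, yb = pseudo[gi, a_mask], pseudo[gi, b_mask]
        za, zb = ya.sum(), yb.sum()
        mean_a, mean_b = za / na, zb / nb_
        lfc[gi] = np.log2(mean_b + prior_count) - np.log2(mean_a + prior_count)
        if za + zb > 0:
            # rescale sums to equal group sizes before conditioning
            if na != nb_:
                n_eq = min(na, nb_)
                za_eq, zb_eq = za * n_eq / na, zb * n_eq / nb_
                pvals[gi] = _exact_nb_pvalue(za_eq, zb_eq, n_eq, n_eq, r)
            else:
                pvals[gi] = _exact_nb_pvalue(za, zb, na, nb_, r)
    out = pd.DataFrame({"log2fc": lfc, "p": pvals})
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out


def differential_test(count_table: pd.DataFrame, input_cols: list[str],
                      ip_cols: list[str], adjp_max: float = DEFAULT_ADJP,
                      lfc_min: float = DEFAULT_LFC,
                      phi: float | None = None) -> pd.DataFrame:
    """Differential interaction analysis on a per-RNA replicate count table.

    ``count_table`` is indexed by gene id with one column per replicate.
    Returns gene, log2FC (IP over Input), p, adjusted p and the call
    ``ip_enriched`` / ``input_enriched`` / ``ns`` at the configured cutoffs.
    """
    cols = input_cols + ip_cols
    x = count_table[cols].to_numpy(dtype=float)
    groups = np.array(["input"] * len(input_cols) + ["ip"] * len(ip_cols))
    res = nb_test(x, groups, phi=phi)
    res.insert(0, "gene_id", count_table.index.to_numpy())
    res["call"] = "ns"
    hit = (res["adj_p"] <= adjp_max) & (res["log2fc"].abs() >= lfc_min)
    res.loc[hit & (res["log2fc"] > 0), "call"] = "ip_enriched"
    res.loc[hit & (res["log2fc"] < 0), "call"] = "input_enriched"
    return res


def build_special_sets(input_species: set[str], ip_species: set[str],
                       diff: pd.DataFrame) -> SpecialSets:
    """Combine capture uniqueness with differential calls into Special sets.

    A condition's unique RNAs are those captured only there; its enriched
    RNAs come from the differential calls; special = unique | enriched.
    """
    unique = {"input": set(input_species) - set(ip_species),
              "ip": set(ip_species) - set(input_species)}
    enriched = {
        "input": set(diff.loc[diff["call"] == "input_enriched", "gene_id"]),
        "ip": set(diff.loc[diff["call"] == "ip_enriched", "gene_id"]),
    }
    return SpecialSets(unique=unique, enriched=enriched)
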