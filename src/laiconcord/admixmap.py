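"""Mixed-model admixture mapping: null model, per-locus score tests,
multiple-testing thresholds, and cross-channel top-hit comparison.

The null model is a linear mixed model

    y = X beta + u_household + u_block + u_kinship + eps

with independent Gaussian random effects: household and census-block effects
shared within their groups, a polygenic effect with covariance
``sigma_k^2 * 2K`` (K the kinship matrix), and residual noise.  Variance
components are estimated by REML with non-negativity constraints; components
estimated at the zero boundary are dropped and the model refit.  Local
ancestry counts are then tested one locus at a time with the score test

    U = g' V^-1 (y - X beta),   Var(U) = g' P g,   U^2 / Var(U) ~ chi^2_1,

where P is the REML projection; only the null fit is needed, which is what
makes genome-wide scans cheap.

The combined random-effect covariance is block-diagonal over the connected
components of the household/block/kinship sparsity pattern (households nest
in census blocks and sibships in households for the cohorts simulated here),
and the implementation factorizes per component — exact, and fast enough for
repeated REML fits at n in the thousands.  A dense kinship simply yields one
large component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.linalg import cho_factor, cho_solve, qr
from scipy.sparse.csgraph import connected_components

from .containers import IntervalCallSet, SnpCallSet
from .simulate import PhenotypeTable

DEFAULT_COVARIATES = ["age", "sex", "center", "group", "egfr",
                      "pc1", "pc2", "pc3", "pc4", "pc5"]
DEFAULT_TESTED_ANCESTRIES = ["African", "Amerindian"]


class ModelError(ValueError):
    """Invalid model inputs (rank deficiency, non-PSD kinship, ...)."""


# ---------------------------------------------------------------------------
# design encoding
# ---------------------------------------------------------------------------


def encode_design(data: pd.DataFrame, covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix: intercept + numerics + dummy-coded factors."""
    cols = [pd.Series(np.ones(len(data)), name="intercept")]
    for cov in covariates:
        series = data[cov]
        if isinstance(series.dtype, pd.CategoricalDtype) or series.dtype == object:
            dummies = pd.get_dummies(series, prefix=cov, drop_first=True, dtype=float)
            cols.extend(dummies[c] for c in dummies.columns)
        else:
            cols.append(series.astype(float))
    X = np.column_stack([np.asarray(c, dtype=float) for c in cols])
    names = [c.name for c in cols]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(names[piv[i]] for i in range(rank, X.shape[1]))
        raise ModelError(f"rank-deficient covariate matrix; collinear columns: {bad}")
    return X, names


# ---------------------------------------------------------------------------
# block-diagonal covariance structure
# ---------------------------------------------------------------------------


class _CovStructure:
    """Random-effect component matrices split over connected components."""

    def __init__(self, n: int, components: dict[str, sparse.csr_matrix]):
        self.n = n
        self.names = list(components)
        union = sparse.identity(n, format="csr")
        for mat in components.values():
            union = union + (abs(mat) > 0).astype(np.int8)
        _, labels = connected_components(union, directed=False)
        order = np.argsort(labels, kind="stable")
        bounds = np.flatnonzero(np.r_[True, np.diff(labels[order]) != 0, True])
        self.blocks = [order[bounds[i]:bounds[i + 1]] for i in range(len(bounds) - 1)]
        self.block_mats: list[list[np.ndarray]] = []
        for idx in self.blocks:
            mats = []
            for name in self.names:
                sub = components[name][idx][:, idx].toarray()
                mats.append(sub)
            self.block_mats.append(mats)

    def check_psd(self, name: str) -> None:
        k = self.names.index(name)
        for idx, mats in zip(self.blocks, self.block_mats):
            m = mats[k]
            if m.any():
                w = np.linalg.eigvalsh(m)
                if w.min() < -1e-6 * max(1.0, w.max()):
                    raise ModelError(f"component {name!r} is not positive semi-definite")


def _grouping_matrix(labels: np.ndarray) -> sparse.csr_matrix:
    labels = np.asarray(labels)
    codes, _ = pd.factorize(labels)
    Z = sparse.csr_matrix(
        (np.ones(len(codes)), (np.arange(len(codes)), codes)),
        shape=(len(codes), codes.max() + 1),
    )
    return (Z @ Z.T).tocsr()


# ---------------------------------------------------------------------------
# null model fit
# ---------------------------------------------------------------------------


@dataclass
class NullModelFit:
    """REML null-model fit exposing the projection used by every score test."""

    beta: np.ndarray
    beta_names: list[str]
    variance_components: dict[str, float]   # includes "residual"
    sample_ids: list[str]
    n: int
    converged: bool
    n_iter: int
    reml_criterion: float
    dropped_components: list[str] = field(default_factory=list)
    # projection machinery
    _X: np.ndarray = None
    _y: np.ndarray = None
    _Py: np.ndarray = None                  # V^-1 (y - X beta)
    _ViX: np.ndarray = None                 # V^-1 X
    _A: np.ndarray = None                   # (X' V^-1 X)^-1
    _blocks: list | None = None             # None -> V = residual * I
    _chols: list | None = None
    _resid_var: float = 1.0

    def v_solve(self, M: np.ndarray) -> np.ndarray:
        """Solve V x = M (columnwise) at the fitted variance components."""
        if self._blocks is None:
            return M / self._resid_var
        out = np.empty_like(M, dtype=float)
        for idx, ch in zip(self._blocks, self._chols):
            out[idx] = cho_solve(ch, M[idx])
        return out

    @property
    def marginal_residuals(self) -> np.ndarray:
        return self._y - self._X @ self.beta


def _reml_eval(theta: np.ndarray, struct: _CovStructure, X: np.ndarray, y: np.ndarray,
               want_artifacts: bool = False):
    """-2 restricted log-likelihood (up to a constant) and its gradient.

    theta = (component variances..., residual variance)."""
    n, p = X.shape
    comp_vars, resid = theta[:-1], theta[-1]
    logdetV = 0.0
    ViX = np.empty((n, p))
    Viy = np.empty(n)
    chols, vinvs = [], []
    for idx, mats in zip(struct.blocks, struct.block_mats):
        m = len(idx)
        V = resid * np.eye(m)
        for c, mat in enumerate(mats):
            if comp_vars[c] != 0.0:
                V += comp_vars[c] * mat
        ch = cho_factor(V, lower=True)
        logdetV += 2.0 * np.log(np.diag(ch[0])).sum()
        vinv = cho_solve(ch, np.eye(m))
        ViX[idx] = vinv @ X[idx]
        Viy[idx] = vinv @ y[idx]
        chols.append(ch)
        vinvs.append(vinv)
    XtViX = X.T @ ViX
    XtViy = X.T @ Viy
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise ModelError("X' V^-1 X not positive definite")
    A = np.linalg.inv(XtViX)
    beta = A @ XtViy
    Py = Viy - ViX @ beta
    f = logdetV + logdetXtViX + float(y @ Viy - XtViy @ beta)

    grad = np.empty(len(theta))
    for c in range(len(theta)):
        t1 = t2w = 0.0
        W = np.zeros((p, p))
        t3 = 0.0
        for b, (idx, mats) in enumerate(zip(struct.blocks, struct.block_mats)):
            Mcb = mats[c] if c < len(comp_vars) else np.eye(len(idx))
            vinv = vinvs[b]
            t1 += float((vinv * Mcb).sum())
            VX = ViX[idx]
            W += VX.T @ Mcb @ VX
            t3 += float(Py[idx] @ Mcb @ Py[idx])
        t2w = float((A * W).sum())
        grad[c] = t1 - t2w - t3
    if want_artifacts:
        return f, grad, {"beta": beta, "A": A, "Py": Py, "ViX": ViX, "chols": chols}
    return f, grad


def fit_null_model(
    phenotypes: PhenotypeTable | pd.DataFrame,
    outcome: str = "phenotype",
    covariates: list[str] | None = None,
    kinship: np.ndarray | None = None,
    household: str | None = "household",
    block: str | None = "block",
    drop_tol: float = 1e-6,
    max_iter: int = 500,
) -> NullModelFit:
    """Fit the REML null mixed model with household/block/kinship random effects."""
    if isinstance(phenotypes, PhenotypeTable):
        data = phenotypes.data
        if kinship is None:
            kinship = phenotypes.kinship
    else:
        data = phenotypes
    if covariates is None:
        covariates = [c for c in DEFAULT_COVARIATES if c in data.columns]
    y = data[outcome].to_numpy(dtype=float)
    n = len(y)
    X, names = encode_design(data, covariates)

    components: dict[str, sparse.csr_matrix] = {}
    if household is not None and household in data.columns:
        components["household"] = _grouping_matrix(data[household].to_numpy())
    if block is not None and block in data.columns:
        components["block"] = _grouping_matrix(data[block].to_numpy())
    if kinship is not None:
        rel = 2.0 * np.asarray(kinship, dtype=float)
        rel[np.abs(rel) < 1e-12] = 0.0
        components["kinship"] = sparse.csr_matrix(rel)

    scale = float(np.var(y)) or 1.0
    active = list(components)
    dropped: list[str] = []
    while True:
        if not active:
            # pure fixed-effects model: closed-form REML
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            sigma2 = float(resid @ resid) / (n - X.shape[1])
            A = np.linalg.inv(X.T @ X) * sigma2
            fit = NullModelFit(
                beta=beta, beta_names=names,
                variance_components={**{c: 0.0 for c in components}, "residual": sigma2},
                sample_ids=list(data["sample_id"]) if "sample_id" in data else
                [str(i) for i in range(n)],
                n=n, converged=True, n_iter=0,
                reml_criterion=float((n - X.shape[1]) * np.log(sigma2)),
                dropped_components=dropped,
                _X=X, _y=y, _Py=resid / sigma2, _ViX=X / sigma2, _A=A,
                _blocks=None, _chols=None, _resid_var=sigma2,
            )
            return fit

        struct = _CovStructure(n, {c: components[c] for c in active})
        if "kinship" in active:
            struct.check_psd("kinship")
        k = len(active)
        theta0 = np.r_[np.full(k, 0.4 * scale / k), 0.6 * scale]
        bounds = [(0.0, None)] * k + [(1e-8 * scale, None)]
        res = optimize.minimize(
            lambda t: _reml_eval(t, struct, X, y), theta0, jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
        )
        theta = res.x
        at_zero = [active[i] for i in range(k) if theta[i] < drop_tol * scale]
        if not at_zero:
            break
        dropped.extend(at_zero)
        active = [c for c in active if c not in at_zero]

    f, _, art = _reml_eval(theta, struct, X, y, want_artifacts=True)
    varcomps = {c: 0.0 for c in components}
    for i, c in enumerate(active):
        varcomps[c] = float(theta[i])
    varcomps["residual"] = float(theta[-1])
    return NullModelFit(
        beta=art["beta"], beta_names=names, variance_components=varcomps,
        sample_ids=list(data["sample_id"]) if "sample_id" in data else
        [str(i) for i in range(n)],
        n=n, converged=bool(res.success), n_iter=int(res.nit),
        reml_criterion=float(f), dropped_components=dropped,
        _X=X, _y=y, _Py=art["Py"], _ViX=art["ViX"], _A=art["A"],
        _blocks=struct.blocks, _chols=art["chols"], _resid_var=float(theta[-1]),
    )


# ---------------------------------------------------------------------------
# score tests and genome scans
# ---------------------------------------------------------------------------


@dataclass
class ScoreTestResult:
    locus_id: str
    ancestry: str
    statistic: float
    p_value: float
    direction: int
    n: int
    testable: bool


def _score_batch(null: NullModelFit, G: np.ndarray):
    """Score statistics for the columns of G (n x L). Returns (U, varU)."""
    ViG = null.v_solve(G)
    U = G.T @ null._Py
    XtViG = null._X.T @ ViG
    varU = np.einsum("nl,nl->l", G, ViG) - np.einsum("pl,pq,ql->l", XtViG, null._A, XtViG)
    return U, varU, np.einsum("nl,nl->l", G, ViG)


def score_test(null: NullModelFit, ancestry_counts: np.ndarray,
               locus_id: str = "locus", ancestry: str = "") -> ScoreTestResult:
    """Single-locus score test of a diploid ancestry count vector."""
    g = np.asarray(ancestry_counts, dtype=float)
    if len(g) != null.n:
        raise ModelError("ancestry counts do not align with the fitted samples")
    U, varU, gViG = _score_batch(null, g[:, None])
    u, v = float(U[0]), float(varU[0])
    if v <= 1e-8 * max(float(gViG[0]), 1e-300):
        return ScoreTestResult(locus_id, ancestry, np.nan, np.nan, 0, null.n, False)
    stat = u * u / v
    return ScoreTestResult(locus_id, ancestry, float(stat),
                           float(stats.chi2.sf(stat, 1)), int(np.sign(u)), null.n, True)


def _locus_frame(calls: SnpCallSet | IntervalCallSet):
    if isinstance(calls, SnpCallSet):
        ids = calls.variant_ids
        pos = calls.positions
        end = calls.positions + 1
    else:
        ids = np.array([f"{c}:{s + 1}-{e}" for c, s, e in
                        zip(calls.chroms, calls.starts, calls.ends)], dtype=object)
        pos = calls.starts
        end = calls.ends
    return ids, pos, end


def scan(null: NullModelFit, calls: SnpCallSet | IntervalCallSet,
         ancestries: list[str] | None = None) -> pd.DataFrame:
    """Score-test every locus for each tested ancestry; deterministic order."""
    if ancestries is None:
        ancestries = [a for a in DEFAULT_TESTED_ANCESTRIES if a in calls.ancestry_labels]
    if calls.sample_ids != null.sample_ids:
        order = [calls.sample_ids.index(s) for s in null.sample_ids]
    else:
        order = slice(None)
    ids, pos, end = _locus_frame(calls)
    frames = []
    for anc in ancestries:
        k = calls.ancestry_labels.index(anc)
        G = calls.counts[:, order, k].T.astype(float)    # n x L
        U, varU, gViG = _score_batch(null, G)
        testable = varU > 1e-8 * np.maximum(gViG, 1e-300)
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = np.where(testable, U * U / np.where(testable, varU, 1.0), np.nan)
        frames.append(pd.DataFrame({
            "chrom": calls.chroms, "pos": pos, "end": end, "locus_id": ids,
            "ancestry": anc, "statistic": stat,
            "p_value": np.where(testable, stats.chi2.sf(stat, 1), np.nan),
            "direction": np.sign(U).astype(int), "n": null.n, "testable": testable,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["ancestry", "chrom", "pos"], kind="stable").reset_index(drop=True)


def genomic_inflation(scan_df: pd.DataFrame) -> float:
    """Inflation factor lambda: median observed statistic over its null median."""
    s = scan_df.loc[scan_df["testable"], "statistic"]
    return float(np.median(s) / stats.chi2.ppf(0.5, 1))


# ---------------------------------------------------------------------------
# ancestry collapse (7 -> 3 majors + other)
# ---------------------------------------------------------------------------


def collapse_ancestries(calls: SnpCallSet | IntervalCallSet,
                        keep: list[str] = ("African", "Amerindian", "European"),
                        other_label: str = "other"):
    """Keep the major ancestries and sum all remaining ones into one class."""
    keep = [a for a in keep if a in calls.ancestry_labels]
    keep_idx = [calls.ancestry_labels.index(a) for a in keep]
    rest_idx = [i for i in range(calls.n_ancestries) if i not in keep_idx]
    new_counts = np.concatenate(
        [calls.counts[:, :, keep_idx],
         calls.counts[:, :, rest_idx].sum(axis=2, keepdims=True, dtype=np.int8)], axis=2,
    )
    labels = list(keep) + [other_label]
    if isinstance(calls, SnpCallSet):
        haps = None
        if calls.haps is not None:
            remap = np.full(calls.n_ancestries, len(keep), dtype=np.int8)
            for new_k, old_k in enumerate(keep_idx):
                remap[old_k] = new_k
            haps = remap[calls.haps]
        return SnpCallSet(calls.chroms, calls.positions, calls.variant_ids, new_counts,
                          calls.maf, calls.r2, list(calls.sample_ids), labels, haps=haps)
    return IntervalCallSet(calls.chroms, calls.starts, calls.ends, new_counts,
                           list(calls.sample_ids), labels)


# ---------------------------------------------------------------------------
# multiple-testing thresholds
# ---------------------------------------------------------------------------


@dataclass
class ThresholdEstimate:
    method: str
    alpha: float
    threshold: float
    m_eff: int | None = None
    n_permutations: int | None = None


def _effective_loci(counts: np.ndarray, chroms: np.ndarray, corr_threshold: float) -> int:
    """Greedy count of independent loci: a new independent locus starts when
    the correlation with the current anchor falls below the cut.

    Counts are centered per individual (subtracting twice the individual's
    global proportion) first; otherwise between-individual variation in
    genome-wide ancestry keeps distant loci correlated and masks the decay
    of the tract-level dependence the threshold should reflect.
    """
    counts = counts.astype(float)
    counts = counts - counts.mean(axis=0, keepdims=True)  # per-individual global mean
    m = 0
    for chrom in dict.fromkeys(chroms):
        rows = np.flatnonzero(chroms == chrom)
        C = counts[rows]                          # L x n
        sd = C.std(axis=1)
        anchor = None
        for j in range(len(rows)):
            if sd[j] == 0:
                continue
            if anchor is None:
                anchor, m = j, m + 1
                continue
            r = np.corrcoef(C[anchor], C[j])[0, 1]
            if abs(r) < corr_threshold:
                anchor, m = j, m + 1
    return m


def significance_threshold(
    calls: SnpCallSet | IntervalCallSet,
    method: str = "bonferroni_effective",
    alpha: float = 0.05,
    ancestries: list[str] | None = None,
    corr_threshold: float = 0.1,
    null: NullModelFit | None = None,
    B: int = 500,
    seed: int = 0,
) -> ThresholdEstimate:
    """Genome-wide significance threshold for the admixture-mapping scan.

    ``bonferroni_effective`` divides alpha by an effective number of
    independent loci estimated from the decay of inter-locus local-ancestry
    correlation; ``permutation`` permutes null-model residuals B times and
    takes the alpha-quantile of the minimum p-value.
    """
    if ancestries is None:
        ancestries = [a for a in DEFAULT_TESTED_ANCESTRIES if a in calls.ancestry_labels]
    if method == "bonferroni_effective":
        m_eff = 1
        for anc in ancestries:
            k = calls.ancestry_labels.index(anc)
            m_eff = max(m_eff, _effective_loci(calls.counts[:, :, k], calls.chroms,
                                               corr_threshold))
        return ThresholdEstimate(method, alpha, alpha / m_eff, m_eff=m_eff)
    if method == "permutation":
        if null is None:
            raise ValueError("permutation threshold requires the fitted null model")
        if B < 100:
            raise ValueError("permutation threshold requires B >= 100")
        if calls.sample_ids != null.sample_ids:
            order = [calls.sample_ids.index(s) for s in null.sample_ids]
        else:
            order = slice(None)
        Gs = [calls.counts[:, order, calls.ancestry_labels.index(a)].T.astype(float)
              for a in ancestries]
        G = np.concatenate(Gs, axis=1)
        ViG = null.v_solve(G)
        XtViG = null._X.T @ ViG
        varU = np.einsum("nl,nl->l", G, ViG) - np.einsum(
            "pl,pq,ql->l", XtViG, null._A, XtViG)
        gvig = np.einsum("nl,nl->l", G, ViG)
        ok = varU > 1e-8 * np.maximum(gvig, 1e-300)
        PG = ViG - null._ViX @ (null._A @ XtViG)
        PG, varU = PG[:, ok], varU[ok]
        # permute on the whitened scale where residuals are exchangeable:
        # y = X beta + L e with V = L L', so U_j = (L' P G_j)' e and
        # P V P = P makes Var(U_j) = g_j' P g_j under permutation of e
        from scipy.linalg import solve_triangular

        resid = null.marginal_residuals
        W = np.empty_like(PG)
        e = np.empty(null.n)
        if null._blocks is None:
            root = np.sqrt(null._resid_var)
            W[:] = root * PG
            e[:] = resid / root
        else:
            for idx, ch in zip(null._blocks, null._chols):
                L = np.tril(ch[0])
                W[idx] = L.T @ PG[idx]
                e[idx] = solve_triangular(L, resid[idx], lower=True)
        rng = np.random.default_rng(seed)
        minp = np.empty(B)
        for b in range(B):
            u = W.T @ rng.permutation(e)
            statb = u * u / varU
            minp[b] = stats.chi2.sf(statb.max(), 1)
        return ThresholdEstimate(method, alpha, float(np.quantile(minp, alpha)),
                                 n_permutations=B)
    raise ValueError(f"unknown threshold method {method!r}")


# ---------------------------------------------------------------------------
# cross-channel / cross-batch top-hit comparison
# ---------------------------------------------------------------------------


def compare_top_hits(scans: dict[str, pd.DataFrame], regions: pd.DataFrame) -> pd.DataFrame:
    """Most significant locus per (region, scan, ancestry): the machine
    analogue of a discovery/replication comparison table.

    ``scans`` maps a label such as ``"snp/discovery"`` to a scan frame;
    ``regions`` needs columns ``chrom, start, end`` (half-open).  Ties on
    p-value break by position; regions where every locus is untestable yield
    a flagged empty cell.
    """
    rows = []
    for ridx, region in regions.reset_index(drop=True).iterrows():
        for label, df in scans.items():
            hit = df[(df["chrom"] == region["chrom"])
                     & (df["pos"] < region["end"]) & (df["end"] > region["start"])]
            for anc, grp in hit.groupby("ancestry", sort=True):
                testable = grp[grp["testable"]]
                if testable.empty:
                    rows.append({"region": ridx, "chrom": region["chrom"],
                                 "start": region["start"], "end": region["end"],
                                 "scan": label, "ancestry": anc, "top_locus": None,
                                 "top_pos": np.nan, "p_value": np.nan,
                                 "all_untestable": True})
                    continue
                best = testable.sort_values(["p_value", "pos"], kind="stable").iloc[0]
                rows.append({"region": ridx, "chrom": region["chrom"],
                             "start": region["start"], "end": region["end"],
                             "scan": label, "ancestry": anc,
                             "top_locus": best["locus_id"], "top_pos": int(best["pos"]),
                             "p_value": float(best["p_value"]), "all_untestable": False})
    return pd.DataFrame(rows)
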