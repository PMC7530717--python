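"""Simulation study orchestration: scenarios, replicates, FPR/power/AUC.

A *scenario* fixes the causal architecture class (number of causal variants
k, causal effect b_E, pleiotropy effect b_U, pleiotropy mode) and the cohort
sizes; each replicate redraws the causal variant sets, effect sizes and
phenotypes, scans the exposure cohort, selects instruments against the LD
reference cohort, and runs every requested estimator on the outcome cohort.

The full grid enumerates k in 1..10, b_E in {0, 0.05, 0.1, 0.2, 0.4} and
b_U in {0, 0.4} — 100 scenarios per pleiotropy mode; the desk-scale default
restricts k to {1, 3, 5, 10}.

Genotype cohorts are simulated once per region and shared across replicates
(and optionally across scenarios); per-replicate randomness covers the
architectures and phenotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import assoc, coloc, genotype_sim, iv_selection, mrlink, mr_methods
from .genotype_sim import GenotypeMatrix, LDMatrix
from .mrlink import MRResult
from .phenotype_sim import (
    InfeasibleArchitectureError,
    select_causal_sets,
    simulate_phenotypes,
)

__all__ = [
    "ScenarioConfig",
    "ScenarioMetrics",
    "RegionCache",
    "make_region",
    "run_scenario",
    "apply_calibration",
    "compute_metrics",
    "auc_scores",
    "paper_grid",
    "desk_grid",
]

DEFAULT_COHORT_SIZES = (15_000, 5_000, 5_000)  # outcome, exposure, LD reference
FULL_KS = tuple(range(1, 11))
DESK_KS = (1, 3, 5, 10)
B_E_GRID = (0.0, 0.05, 0.1, 0.2, 0.4)
B_U_GRID = (0.0, 0.4)
DEFAULT_METHODS = ("mr_link", "ivw", "mr_egger", "lda_mr_egger", "coloc")


@dataclass
class ScenarioConfig:
    """One cell of the simulation grid."""

    k_causal: int
    b_E: float
    b_U: float
    mode: str = "ld"
    overlap_fraction: float = 1.0
    cohort_sizes: tuple[int, int, int] = DEFAULT_COHORT_SIZES
    n_reps: int = 150
    iv_method: str = "cojo"
    seed: int = 0
    n_variants: int = 1000
    lam: float | None = None
    methods: tuple[str, ...] = DEFAULT_METHODS
    presso_n_sim: int = 400

    def label(self) -> str:
        return (
            f"k={self.k_causal},bE={self.b_E},bU={self.b_U},"
            f"mode={self.mode},iv={self.iv_method}"
        )


@dataclass
class ScenarioMetrics:
    """Per-method decision summary for one scenario."""

    config: ScenarioConfig
    per_method: dict  # method -> {n_estimates, fpr_or_power, reported}

    def table(self) -> pd.DataFrame:
        rows = [
            {"method": m, **vals, "scenario": self.config.label()}
            for m, vals in self.per_method.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class RegionCache:
    """Simulated cohorts plus everything reusable across replicates."""

    G_out: GenotypeMatrix
    G_exp: GenotypeMatrix
    G_ref: GenotypeMatrix
    ld_ref: LDMatrix
    X_exp_std: np.ndarray  # float64, exposure cohort standardized dosages
    X_out_std: np.ndarray
    gram_out: np.ndarray  # X_out_std' X_out_std
    seed: int = 0


def make_region(
    n_variants: int = 1000,
    cohort_sizes: tuple[int, int, int] = DEFAULT_COHORT_SIZES,
    seed: int = 0,
    maf_min: float = 0.01,
    panel_haplotypes: int = 400,
    oversample: float = 1.25,
    panel_kwargs: dict | None = None,
) -> RegionCache:
    """Simulate a region's haplotype panel and the three cohorts.

    ``n_variants`` counts variants *after* the MAF filter; the panel is built
    with headroom (``oversample``) and trimmed.  Variants monomorphic in any
    cohort are dropped everywhere so LD and scans stay well defined.
    """
    rng = np.random.default_rng(seed)
    n_raw = int(np.ceil(n_variants * oversample))
    panel = genotype_sim.build_panel(
        panel_haplotypes, n_raw, seed=rng, **(panel_kwargs or {})
    )
    n_out, n_exp, n_ref = cohort_sizes
    G_out, G_exp, G_ref = genotype_sim.expand_cohorts(
        panel,
        [n_out, n_exp, n_ref],
        seed=rng,
        labels=["outcome", "exposure", "ld_ref"],
    )
    keep = np.flatnonzero(
        (G_out.maf() >= maf_min) & (G_exp.maf() >= maf_min) & (G_ref.maf() >= maf_min)
    )[:n_variants]
    G_out, G_exp, G_ref = (g.take_variants(keep) for g in (G_out, G_exp, G_ref))

    ld_ref = genotype_sim.ld_matrix(G_ref)
    X_exp = G_exp.standardized().astype(np.float64)
    X_out32 = G_out.standardized()
    gram = (X_out32.T @ X_out32).astype(np.float64)
    return RegionCache(
        G_out=G_out,
        G_exp=G_exp,
        G_ref=G_ref,
        ld_ref=ld_ref,
        X_exp_std=X_exp,
        X_out_std=X_out32.astype(np.float64),
        gram_out=gram,
        seed=seed,
    )


def _batched_scan(X_std: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized simple-regression scan of every Y column on every X column.

    Returns (beta, se, p) of shape (m, n_reps), on the standardized-genotype
    scale with the phenotype on its raw scale.
    """
    n, m = X_std.shape
    Yc = Y - Y.mean(axis=0)
    B = (X_std.T @ Yc) / n
    var_y = np.einsum("ij,ij->j", Yc, Yc) / n
    rss_n = np.maximum(var_y[None, :] - B**2, 0.0)
    dof = n - 2
    SE = np.maximum(np.sqrt(rss_n / dof), np.finfo(float).tiny)
    P = 2.0 * sps.t.sf(np.abs(B / SE), dof)
    P = np.clip(P, np.finfo(float).tiny, 1.0)
    return B, SE, P


def _stats_frame(G: GenotypeMatrix, b, se, p, n: int) -> assoc.SummaryStats:
    table = pd.DataFrame(
        {
            "SNP": G.variant_ids,
            "A1": G.a1,
            "A2": G.a2,
            "freq": G.allele_frequency(),
            "b": b,
            "se": se,
            "p": p,
            "N": n,
            "valid": np.isfinite(se),
        }
    )
    return assoc.SummaryStats(table=table)


def run_scenario(cfg: ScenarioConfig, cache: RegionCache | None = None) -> list[dict]:
    """Run every replicate of one scenario; returns one record dict per rep.

    Each record maps method name to its :class:`MRResult` (or, for coloc, a
    dict with the posterior and decision score), plus bookkeeping keys
    ``rep`` and ``k``.  Method failures are recorded as result statuses and
    never dropped.
    """
    if cache is None:
        cache = make_region(cfg.n_variants, cfg.cohort_sizes, seed=cfg.seed)
    n_out = cache.G_out.n_individuals
    n_exp = cache.G_exp.n_individuals
    m = cache.G_out.n_variants

    ss = np.random.SeedSequence(cfg.seed)
    rep_seeds = ss.spawn(cfg.n_reps)

    # draw all architectures and phenotypes first so scans can be batched
    archs, Y_exp, Y_out, feasible = [], [], [], []
    for i in range(cfg.n_reps):
        rng = np.random.default_rng(rep_seeds[i])
        try:
            arch = select_causal_sets(
                cache.ld_ref, cfg.k_causal, mode=cfg.mode,
                overlap_fraction=cfg.overlap_fraction, seed=rng,
            )
        except InfeasibleArchitectureError:
            feasible.append(False)
            archs.append(None)
            Y_exp.append(np.zeros(n_exp))
            Y_out.append(np.zeros(n_out))
            continue
        feasible.append(True)
        archs.append(arch)
        ph_exp = simulate_phenotypes(cache.G_exp, arch, cfg.b_E, cfg.b_U, seed=rng)
        ph_out = simulate_phenotypes(cache.G_out, arch, cfg.b_E, cfg.b_U, seed=rng)
        Y_exp.append(ph_exp.y_E)
        Y_out.append(ph_out.y_O)
    Y_exp = np.column_stack(Y_exp)
    Y_out = np.column_stack(Y_out)

    # exposure scan standardizes the phenotype (eQTL-like scale)
    sd_exp = Y_exp.std(axis=0)
    sd_exp[sd_exp == 0] = 1.0
    B_e, SE_e, P_e = _batched_scan(cache.X_exp_std, Y_exp / sd_exp)
    B_o, SE_o, P_o = _batched_scan(cache.X_out_std, Y_out)
    Yc_out = Y_out - Y_out.mean(axis=0)
    XtY_out = cache.X_out_std.T @ Yc_out  # m x reps; equals n * B_o
    yty_out = np.einsum("ij,ij->j", Yc_out, Yc_out)
    sd_out = Y_out.std(axis=0)

    selector = (
        iv_selection.cojo_select if cfg.iv_method == "cojo" else iv_selection.clump_select
    )
    need_ivs = any(
        m in cfg.methods
        for m in ("mr_link", "ivw", "mr_egger", "lda_mr_egger", "mr_presso")
    )
    records = []
    for i in range(cfg.n_reps):
        rec: dict = {"rep": i, "k": cfg.k_causal, "feasible": feasible[i]}
        if not feasible[i]:
            for meth in cfg.methods:
                rec[meth] = MRResult(method=meth, status="no_solution")
            records.append(rec)
            continue

        exp_stats = _stats_frame(cache.G_exp, B_e[:, i], SE_e[:, i], P_e[:, i], n_exp)
        if need_ivs:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                ivs = selector(exp_stats, cache.ld_ref)
            rec["n_ivs"] = len(ivs)

        if "mr_link" in cfg.methods:
            tags = mrlink.select_tags(cache.ld_ref, ivs)
            rec["mr_link"] = mrlink.mrlink_fit_from_grams(
                cache.gram_out, XtY_out[:, i], float(yty_out[i]), n_out,
                ivs, tags, lam=cfg.lam,
            )

        summary_methods = [
            mth for mth in cfg.methods
            if mth in ("ivw", "mr_egger", "lda_mr_egger", "mr_presso")
        ]
        if summary_methods:
            if len(ivs):
                s = ivs.indices
                sign = np.where(B_e[s, i] < 0, -1.0, 1.0)
                data = mr_methods.HarmonizedIVData(
                    variant_ids=cache.G_exp.variant_ids[s],
                    beta_exp=B_e[s, i] * sign,
                    se_exp=SE_e[s, i],
                    beta_out=B_o[s, i] * sign,
                    se_out=SE_o[s, i],
                    eaf=cache.G_exp.allele_frequency()[s],
                    ld=cache.ld_ref.r[np.ix_(s, s)] * np.outer(sign, sign),
                )
            else:
                data = None
            for meth in summary_methods:
                if data is None:
                    rec[meth] = MRResult(method=meth, n_ivs=0, status="too_few_ivs")
                elif meth == "ivw":
                    rec[meth] = mr_methods.ivw(data)
                elif meth == "mr_egger":
                    rec[meth] = mr_methods.mr_egger(data)
                elif meth == "lda_mr_egger":
                    rec[meth] = mr_methods.lda_mr_egger(data)
                elif meth == "mr_presso":
                    rec[meth] = mr_methods.mr_presso(
                        data, n_sim=cfg.presso_n_sim,
                        seed=np.random.default_rng(rep_seeds[i]).integers(2**31),
                    )

        if "coloc" in cfg.methods:
            out_stats = _stats_frame(
                cache.G_out, B_o[:, i], SE_o[:, i], P_o[:, i], n_out
            )
            res = coloc.coloc_abf(
                exp_stats, out_stats, sdY1=1.0, sdY2=float(sd_out[i])
            )
            rec["coloc"] = {"pp4": res.pp4, "pp": res.pp}
        records.append(rec)
    return records


def apply_calibration(records: list[dict], null_records: list[dict]) -> None:
    """Fill MR-link calibrated p-values using matched null raw p-values.

    ``null_records`` should come from the matching pleiotropy-free null
    scenario (same k and IV selection, b_E = 0, b_U = 0): the null
    distribution consistent with the estimator's modeling assumptions.
    Records are modified in place.
    """
    null_p = np.array(
        [
            r["mr_link"].p_raw
            for r in null_records
            if "mr_link" in r and r["mr_link"].status == "ok"
        ]
    )
    null_p = null_p[(null_p > 0) & (null_p < 1)]
    if null_p.size < 10:
        raise ValueError("too few successful null runs to calibrate against")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in records:
            res = r.get("mr_link")
            if res is not None and res.status == "ok":
                res.p_calibrated = float(
                    mrlink.calibrate_pvalues(null_p, min(res.p_raw, 1.0 - 1e-16))
                )


def compute_metrics(
    cfg: ScenarioConfig,
    records: list[dict],
    alpha: float = 0.05,
    pp4_threshold: float = 0.9,
    min_estimates: int = 100,
) -> ScenarioMetrics:
    """Fraction of positive decisions per method over successful runs.

    For p-value methods a positive decision is p < alpha (MR-link uses its
    calibrated p when present); for coloc it is PP4 > the threshold.  A
    method's result is flagged unreported when it produced ``min_estimates``
    or fewer successful estimates.
    """
    per_method = {}
    for meth in cfg.methods:
        n_ok = 0
        n_pos = 0
        for r in records:
            res = r.get(meth)
            if res is None:
                continue
            if meth == "coloc":
                n_ok += 1
                n_pos += bool(res["pp4"] > pp4_threshold)
            elif res.status == "ok":
                n_ok += 1
                n_pos += bool(res.p < alpha)
        per_method[meth] = {
            "n_estimates": n_ok,
            "fpr_or_power": (n_pos / n_ok) if n_ok else np.nan,
            "reported": n_ok > min_estimates,
        }
    return ScenarioMetrics(config=cfg, per_method=per_method)


def auc_scores(null_scores, causal_scores) -> float:
    """Probability a random causal-scenario score exceeds a random null score.

    Mann-Whitney formulation with ties counted half; scores are PP4 for
    coloc and 1 - p for the p-value methods.
    """
    null_scores = np.asarray(null_scores, dtype=float)
    causal_scores = np.asarray(causal_scores, dtype=float)
    if null_scores.size == 0 or causal_scores.size == 0:
        raise ValueError("both score collections must be nonempty")
    from sklearn.metrics import roc_auc_score

    y = np.concatenate([np.zeros(null_scores.size), np.ones(causal_scores.size)])
    return float(roc_auc_score(y, np.concatenate([null_scores, causal_scores])))


def headline_summary(
    seed: int = 1,
    n_reps_null: int = 200,
    n_reps_power: int = 150,
    ks: tuple[int, ...] = DESK_KS,
    b_Es: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4),
    n_variants: int = 1000,
    cohort_sizes: tuple[int, int, int] = DEFAULT_COHORT_SIZES,
    lam: float | None = None,
    progress: bool = False,
) -> dict:
    """Run the headline simulation study and summarize FPR/power per method.

    Covers, per causal-variant count k: pleiotropy-through-LD nulls
    (b_E=0, b_U=0.4), overlap-mode nulls, pleiotropy-free nulls under both IV
    selectors, the LD and overlap causal grids (b_E over ``b_Es``, b_U=0.4)
    for MR-link, and the non-pleiotropic causal grid for colocalization.
    One simulated region is shared by every scenario; architectures, effects
    and phenotypes are redrawn each replicate.  MR-link p-values are
    beta-calibrated per (k, b_U) on the pleiotropy-through-LD null runs.

    Returns a flat dict of summary proportions (medians / extrema over the
    scenario grids) plus the per-scenario tables under ``"per_scenario"``.
    """
    ss = np.random.SeedSequence(seed)

    def next_seed() -> int:
        return int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)

    cache = make_region(n_variants, cohort_sizes, seed=next_seed())

    def run(k, b_E, b_U, mode, reps, methods, iv_method="cojo"):
        cfg = ScenarioConfig(
            k_causal=k, b_E=b_E, b_U=b_U, mode=mode, n_reps=reps,
            iv_method=iv_method, seed=next_seed(), n_variants=n_variants,
            cohort_sizes=cohort_sizes, lam=lam, methods=methods,
        )
        if progress:
            print(f"  scenario {cfg.label()} ({reps} reps)", flush=True)
        return cfg, run_scenario(cfg, cache)

    fpr = {m: [] for m in ("mr_link", "ivw", "coloc")}
    ov_fpr, cojo_fpr, clump_fpr = [], [], []
    ld_power, ov_power, coloc_power = [], [], []
    per_scenario = []

    def frac(cfg, recs, meth):
        met = compute_metrics(cfg, recs, min_estimates=100)
        per_scenario.append(met)
        return met.per_method[meth]["fpr_or_power"]

    for k in ks:
        cfg_ld, ldnull = run(k, 0.0, 0.4, "ld", n_reps_null,
                             ("mr_link", "ivw", "coloc"))
        cfg_ov, ovnull = run(k, 0.0, 0.4, "overlap", n_reps_null, ("mr_link",))
        cfg_cj, clean_cojo = run(k, 0.0, 0.0, "ld", n_reps_null, ("ivw",))
        cfg_cl, clean_clump = run(k, 0.0, 0.0, "ld", n_reps_null, ("ivw",),
                                  iv_method="clump")
        apply_calibration(ldnull, ldnull)
        apply_calibration(ovnull, ldnull)
        fpr["mr_link"].append(frac(cfg_ld, ldnull, "mr_link"))
        fpr["ivw"].append(
            compute_metrics(cfg_ld, ldnull, min_estimates=100).per_method["ivw"][
                "fpr_or_power"
            ]
        )
        fpr["coloc"].append(
            compute_metrics(cfg_ld, ldnull, min_estimates=100).per_method["coloc"][
                "fpr_or_power"
            ]
        )
        ov_fpr.append(frac(cfg_ov, ovnull, "mr_link"))
        cojo_fpr.append(frac(cfg_cj, clean_cojo, "ivw"))
        clump_fpr.append(frac(cfg_cl, clean_clump, "ivw"))

        for b_E in b_Es:
            cfg_c, ldcaus = run(k, b_E, 0.4, "ld", n_reps_power, ("mr_link",))
            apply_calibration(ldcaus, ldnull)
            ld_power.append(frac(cfg_c, ldcaus, "mr_link"))
            cfg_o, ovcaus = run(k, b_E, 0.4, "overlap", n_reps_power, ("mr_link",))
            apply_calibration(ovcaus, ldnull)
            ov_power.append(frac(cfg_o, ovcaus, "mr_link"))
            cfg_p, colcaus = run(k, b_E, 0.0, "ld", n_reps_power, ("coloc",))
            coloc_power.append(frac(cfg_p, colcaus, "coloc"))

    return {
        "mrlink_ld_null_fpr_median": float(np.median(fpr["mr_link"])),
        "mrlink_ld_null_fpr_max": float(np.max(fpr["mr_link"])),
        "ivw_ld_null_fpr_max": float(np.max(fpr["ivw"])),
        "ivw_ld_null_fpr_min": float(np.min(fpr["ivw"])),
        "ivw_clean_null_fpr_median_cojo": float(np.median(cojo_fpr)),
        "ivw_clean_null_fpr_median_clump": float(np.median(clump_fpr)),
        "mrlink_ld_power_max": float(np.max(ld_power)),
        "mrlink_overlap_null_fpr_max": float(np.max(ov_fpr)),
        "mrlink_overlap_power_max": float(np.max(ov_power)),
        "coloc_ld_null_fpr_median": float(np.median(fpr["coloc"])),
        "coloc_nonpleiotropic_power_max": float(np.max(coloc_power)),
        "n_reps_null": n_reps_null,
        "n_reps_power": n_reps_power,
        "per_scenario": per_scenario,
    }


def paper_grid(
    mode: str = "ld",
    ks: tuple[int, ...] = FULL_KS,
    b_Es: tuple[float, ...] = B_E_GRID,
    b_Us: tuple[float, ...] = B_U_GRID,
    **kwargs,
) -> list[ScenarioConfig]:
    """Enumerate the scenario grid (full grid: 10 x 5 x 2 = 100 per mode)."""
    return [
        ScenarioConfig(k_causal=k, b_E=be, b_U=bu, mode=mode, **kwargs)
        for k in ks
        for be in b_Es
        for bu in b_Us
    ]


def desk_grid(mode: str = "ld", **kwargs) -> list[ScenarioConfig]:
    """Reduced grid with k in {1, 3, 5, 10}."""
    return paper_grid(mode=mode, ks=DESK_KS, **kwargs)
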