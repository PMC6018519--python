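"""Hit testing, waterfall ranking, dose-response regression and FDR control.

A compound's primary-screen evidence is its 2-4 normalized replicate-well
means, tested against the plate global average (1 after plate-mean
normalization).  Two test variants are provided:

* the plain one-sample two-sided t-test on the replicate means
  (``null_sd=None``), and
* a vehicle-referenced t-test that estimates both the null center and the
  null spread from the 36 vehicle border wells of the replicate plates
  (``null_sd``/``null_df`` supplied, plus the two-sample standard error when
  ``null_n`` is given).  With only 2-4 replicates the plain test has
  essentially no power at alpha = 0.001 (df <= 3), and after plate-mean
  normalization the null compounds sit at the *vehicle* mean (which drifts
  from 1 when active compounds shift the plate mean); the vehicle wells
  exist precisely to supply both, so the pipeline defaults to the referenced
  variant.

Hits are compounds significant on at least one hit parameter and not flagged
for viability (normalized cell density more than 2 SDs below the global
mean).  Follow-up dose-response is ordinary least squares of the normalized
response on dose with the Benjamini-Hochberg step-up correction applied per
parameter family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import StatsError

DEFAULT_HIT_PARAMETERS = (
    "nuclear_lc3_intensity",
    "cytoplasmic_lc3_intensity",
    "holes_count",
    "nuclear_area",
)
DEFAULT_DOSE_GRID = (1.25, 2.5, 5.0, 10.0, 20.0)


# ---------------------------------------------------------------------------
# Single-compound test
# ---------------------------------------------------------------------------

@dataclass
class CompoundTest:
    p_value: float
    t_statistic: float
    dof: float
    direction: str  # "up" | "down"
    degenerate: bool = False


def test_compound(
    replicate_values: Sequence[float],
    null_value: float = 1.0,
    null_sd: Optional[float] = None,
    null_df: Optional[int] = None,
    null_n: Optional[int] = None,
) -> CompoundTest:
    """Two-sided t-test of the replicate means against ``null_value``.

    With ``null_sd`` omitted this is the one-sample t-test on the 2-4
    replicate values (df = n - 1).  Supplying ``null_sd`` (a pooled per-well
    null SD, e.g. from vehicle wells) and its ``null_df`` switches to the
    referenced test t = (mean - null) / se with ``null_df`` degrees of
    freedom, where se = null_sd * sqrt(1/n + 1/null_n) when the null center
    was itself estimated from ``null_n`` wells (two-sample form), or
    null_sd / sqrt(n) for a fixed null value.  Degenerate cases (zero sample
    variance) follow the convention p = 1 at the null value and p = 0 away
    from it, flagged.
    """
    x = np.asarray(replicate_values, dtype=float)
    if x.size < 2:
        raise StatsError(f"need >= 2 replicate values, got {x.size}")
    mean = float(x.mean())
    direction = "up" if mean > null_value else "down"
    if null_sd is not None:
        if null_df is None or null_df < 1:
            raise StatsError("null_sd requires a positive null_df")
        if null_sd <= 0:
            raise StatsError("null_sd must be > 0")
        inv = 1.0 / x.size + (1.0 / null_n if null_n else 0.0)
        se = null_sd * math.sqrt(inv)
        t = (mean - null_value) / se
        p = 2.0 * stats.t.sf(abs(t), df=null_df)
        return CompoundTest(p_value=float(p), t_statistic=float(t), dof=float(null_df), direction=direction)
    if x.std(ddof=1) == 0.0:
        if mean == null_value:
            return CompoundTest(1.0, 0.0, float(x.size - 1), direction, degenerate=True)
        return CompoundTest(0.0, math.inf, float(x.size - 1), direction, degenerate=True)
    res = stats.ttest_1samp(x, popmean=null_value)
    return CompoundTest(
        p_value=float(res.pvalue),
        t_statistic=float(res.statistic),
        dof=float(x.size - 1),
        direction=direction,
    )


# ---------------------------------------------------------------------------
# Screen-level tests
# ---------------------------------------------------------------------------

def screen_compound_tests(
    normalized_wells: pd.DataFrame,
    parameters: Sequence[str],
    reference: str = "vehicle",
    null_value: float = 1.0,
) -> pd.DataFrame:
    """Test every compound on every parameter across replicate plates.

    ``normalized_wells`` is a long table (one row per well per plate) with
    plate_id, well_id, role, compound_id and normalized parameter columns.
    Each compound's replicate values are its normalized well values across
    the replicate plates.  ``reference='vehicle'`` compares each compound to
    the pooled vehicle wells: null center = overall vehicle mean, null SD
    pooled from the per-plate-centered vehicle wells, two-sample standard
    error (the vehicle border wells are the screen's built-in null);
    ``reference='one_sample'`` uses the plain t-test on the replicates
    against ``null_value``.  Returns one row per compound x parameter with
    replicate values, mean of means, t, p and direction.
    """
    if reference not in ("vehicle", "one_sample"):
        raise StatsError(f"unknown reference {reference!r}")
    df = normalized_wells
    rows = []
    null_sd: dict[str, float] = {}
    null_df: dict[str, int] = {}
    null_center: dict[str, float] = {}
    null_n: dict[str, int] = {}
    if reference == "vehicle":
        veh = df[df["role"] == "vehicle"]
        if veh.empty:
            raise StatsError("vehicle reference requested but no vehicle wells present")
        for p in parameters:
            ss, dof, n_tot, total = 0.0, 0, 0, 0.0
            for _, grp in veh.groupby("plate_id"):
                v = grp[p].dropna().to_numpy(dtype=float)
                if v.size >= 2:
                    ss += float(((v - v.mean()) ** 2).sum())
                    dof += v.size - 1
                n_tot += v.size
                total += float(v.sum())
            if dof < 1 or ss <= 0:
                raise StatsError(f"cannot pool a vehicle null SD for parameter {p!r}")
            null_sd[p] = math.sqrt(ss / dof)
            null_df[p] = dof
            null_center[p] = total / n_tot
            null_n[p] = n_tot

    comp = df[(df["role"] == "compound") & (df["compound_id"] != "")]
    for cid, grp in comp.groupby("compound_id", sort=True):
        for p in parameters:
            values = grp[p].dropna().to_numpy(dtype=float)
            if values.size < 2:
                continue  # fewer than 2 usable replicates: untestable
            if reference == "vehicle":
                res = test_compound(
                    values, null_center[p], null_sd[p], null_df[p], null_n[p]
                )
            else:
                res = test_compound(values, null_value)
            rows.append(
                {
                    "compound_id": cid,
                    "parameter": p,
                    "n_replicates": int(values.size),
                    "replicate_values": list(values),
                    "mean_of_means": float(values.mean()),
                    "sd_of_means": float(values.std(ddof=1)),
                    "t_statistic": res.t_statistic,
                    "dof": res.dof,
                    "p_value": res.p_value,
                    "direction": res.direction,
                    "degenerate": res.degenerate,
                }
            )
    return pd.DataFrame(rows)


def select_hits(
    results: pd.DataFrame,
    alpha: float = 0.001,
    hit_parameters: Sequence[str] = DEFAULT_HIT_PARAMETERS,
    viability_parameter: str = "cell_density",
    viability_rule: str = "significant",
    viability_sd_mult: float = 2.0,
) -> pd.DataFrame:
    """Call hits: significant on >= 1 hit parameter and viable.

    ``results`` is the table from :func:`screen_compound_tests` and must
    include ``viability_parameter`` rows for every compound.  Viability:
    under the default ``viability_rule='significant'`` a compound is flagged
    when it *significantly decreases* normalized cell density (p < alpha,
    direction down); under ``'sd_band'`` when its density mean lies more
    than ``viability_sd_mult`` SDs below the global mean of compound
    densities (the waterfall-band variant, which by construction flags the
    lower tail of null compounds too).  Returns one row per compound with
    hit / viability flags and its best (smallest-p) hit parameter.
    """
    if viability_rule not in ("significant", "sd_band"):
        raise StatsError(f"unknown viability rule {viability_rule!r}")
    dens_rows = results[results["parameter"] == viability_parameter].set_index(
        "compound_id"
    )
    dens = dens_rows["mean_of_means"]
    all_compounds = sorted(results["compound_id"].unique())
    missing = set(all_compounds) - set(dens.index)
    if missing:
        raise StatsError(
            f"viability parameter {viability_parameter!r} missing for "
            f"{len(missing)} compounds, e.g. {sorted(missing)[:3]}"
        )
    thr = float(dens.mean() - viability_sd_mult * dens.std(ddof=1))
    rows = []
    hp = results[results["parameter"].isin(hit_parameters)]
    for cid in all_compounds:
        sub = hp[hp["compound_id"] == cid]
        if sub.empty:
            continue
        best = sub.loc[sub["p_value"].idxmin()]
        if viability_rule == "significant":
            viability_flagged = bool(
                dens_rows.loc[cid, "p_value"] < alpha
                and dens_rows.loc[cid, "direction"] == "down"
            )
        else:
            viability_flagged = bool(dens[cid] < thr)
        significant = bool(best["p_value"] < alpha)
        rows.append(
            {
                "compound_id": cid,
                "best_parameter": best["parameter"],
                "best_p_value": float(best["p_value"]),
                "direction": best["direction"],
                "n_significant_parameters": int((sub["p_value"] < alpha).sum()),
                "normalized_cell_density": float(dens[cid]),
                "viability_flagged": viability_flagged,
                "hit": significant and not viability_flagged,
            }
        )
    return pd.DataFrame(rows)


def waterfall_rank(results: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Rank compounds ascending by mean of replicate means on one parameter.

    Ties break lexicographically by compound id.  Output carries rank, mean
    and the SD of the replicate means (the error bar of a waterfall plot).
    """
    sub = results[results["parameter"] == parameter].copy()
    sub = sub.sort_values(["mean_of_means", "compound_id"], kind="mergesort").reset_index(
        drop=True
    )
    out = sub[["compound_id", "mean_of_means", "sd_of_means", "n_replicates"]].copy()
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


# ---------------------------------------------------------------------------
# Dose-response regression
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseResult:
    compound_id: str
    parameter: str
    slope: float  # per uM
    intercept: float
    p_value: float
    F_statistic: float
    r_squared: float
    dof: int  # n_points - 2
    direction: str  # sign of the slope: "up" | "down"
    constant_response: bool = False
    bh_significant: Optional[bool] = None


def fit_dose_response(
    doses: Sequence[float],
    responses: Sequence[float],
    compound_id: str = "",
    parameter: str = "",
) -> DoseResponseResult:
    """Ordinary least squares of response on dose (simple linear regression).

    Reports the two-sided p-value for slope != 0, the regression F statistic
    (= t^2 in simple regression), r^2 and dof = n - 2.  Requires >= 3 points
    and >= 2 distinct doses.  A constant response is reported as slope 0 and
    r^2 = 0 with ``constant_response`` flagged.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.size != y.size:
        raise StatsError("doses and responses differ in length")
    if d.size < 3:
        raise StatsError(f"need >= 3 points for a defined regression, got {d.size}")
    if np.unique(d).size < 2:
        raise StatsError("all doses identical; slope undefined")
    direction_of = lambda s: "up" if s >= 0 else "down"
    if np.all(y == y[0]):
        return DoseResponseResult(
            compound_id=compound_id,
            parameter=parameter,
            slope=0.0,
            intercept=float(y[0]),
            p_value=1.0,
            F_statistic=0.0,
            r_squared=0.0,
            dof=int(d.size - 2),
            direction="up",
            constant_response=True,
        )
    fit = stats.linregress(d, y)
    t = fit.slope / fit.stderr if fit.stderr > 0 else math.inf
    return DoseResponseResult(
        compound_id=compound_id,
        parameter=parameter,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        F_statistic=float(t * t),
        r_squared=float(fit.rvalue**2),
        dof=int(d.size - 2),
        direction=direction_of(fit.slope),
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment and significance flags at level q.

    adjusted_i = min over j >= i (sorted) of p_(j) * m / j, clipped at 1;
    flags = adjusted <= q; the original order is restored on output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise StatsError("q must be in (0, 1)")
    _, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, adjusted <= q


def dose_response_table(
    followup_wells: pd.DataFrame,
    parameters: Sequence[str],
    q: float = 0.05,
) -> pd.DataFrame:
    """Fit dose-response for every compound x parameter and apply BH per parameter.

    ``followup_wells`` is a long normalized well table with compound_id,
    dose_uM and parameter columns (all replicate wells pooled as regression
    points).  Compounds with < 3 usable doses on a parameter are skipped.
    The BH family is the set of compounds within one parameter.
    """
    rows = []
    comp = followup_wells[followup_wells["role"] == "compound"]
    for param in parameters:
        fits: list[DoseResponseResult] = []
        for cid, grp in comp.groupby("compound_id", sort=True):
            sub = grp[["dose_uM", param]].dropna()
            if sub["dose_uM"].nunique() < 3:
                continue
            fits.append(
                fit_dose_response(
                    sub["dose_uM"].to_numpy(),
                    sub[param].to_numpy(),
                    compound_id=cid,
                    parameter=param,
                )
            )
        if not fits:
            continue
        adjusted, flags = bh_adjust([f.p_value for f in fits], q=q)
        for f, adj, flag in zip(fits, adjusted, flags):
            f.bh_significant = bool(flag)
            rows.append(
                {
                    "compound_id": f.compound_id,
                    "parameter": f.parameter,
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "p_value": f.p_value,
                    "p_adjusted": float(adj),
                    "F": f.F_statistic,
                    "r2": f.r_squared,
                    "dof": f.dof,
                    "slope_sign": f.direction,
                    "constant_response": f.constant_response,
                    "bh_significant": f.bh_significant,
                }
            )
    return pd.DataFrame(rows)
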