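"""TR-FRET coactivator-assay normalization and 4PL dose-response fitting.

A TR-FRET plate reads two emission channels per well: 495 nm (terbium
donor) and 520 nm (fluorescein acceptor).  The working ratio is
acceptor/donor (520/495) — it rises with ligand-induced coactivator
recruitment and cancels well-to-well variation in donor intensity; the
donor/acceptor direction is available as a switch.  Responses are
normalized linearly so that the mean no-agonist control ratio maps to 0%
and the mean reference-agonist ratio at its top concentration maps to
100%.

Dose-response curves follow the four-parameter logistic (4PL) model

    r(c) = lower + (upper - lower) / (1 + (EC50 / c) ** slope)

fitted by least squares on log10 concentration, with the EC50 carried
internally as log10(EC50) for stability.  Wald 95% confidence intervals
come from the parameter covariance (EC50 intervals computed on the log
scale and exponentiated).  Parameter pairs across ligands are compared
with Wald z tests, matching the comparison-of-fitted-parameters style of
drc::compParm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

WELL_ROLES = {"test", "no_agonist", "no_agonist_no_LBD", "agonist_reference"}
Z95 = stats.norm.ppf(0.975)


class FitError(RuntimeError):
    """4PL optimization failed to converge or is degenerate."""


@dataclass
class DoseResponseFit:
    """4PL fit: asymptotes, EC50 (μM), slope, SEs and 95% Wald CIs.

    ``upper`` is the fitted top asymptote on the normalized 0-100% scale
    and doubles as the E_max estimate relative to the reference agonist.
    ``converged`` is False for flagged (flat / non-identifiable) fits,
    whose EC50 is NaN; flagged fits are never silently usable.
    """

    lower: float
    upper: float
    ec50: float
    slope: float
    se: dict = field(default_factory=dict)
    ci95: dict = field(default_factory=dict)
    converged: bool = True
    log10_ec50: float = float("nan")
    se_log10_ec50: float = float("nan")
    n_points: int = 0

    @property
    def emax(self) -> float:
        return self.upper


def serial_dilution(top: float, n_steps: int) -> np.ndarray:
    """Half-dilution series: ``top / 2**i`` for i = 0..n_steps-1 (μM)."""
    if top <= 0:
        raise ValueError("top concentration must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    return top / np.power(2.0, np.arange(n_steps))


def normalize(plate: pd.DataFrame, ratio: str = "520/495",
              qc_acceptor_floor: bool = True) -> pd.DataFrame:
    """Normalize raw channel signals to % activation.

    Requires columns ``ligand, conc_uM, replicate, em495, em520, role``.
    Adds ``ratio`` (working channel ratio) and ``response`` (% activation:
    no-agonist mean -> 0, agonist-reference top-concentration mean -> 100).

    When ``qc_acceptor_floor`` is set and no-LBD control wells exist, test
    wells whose acceptor (520 nm) signal falls below the mean no-LBD
    acceptor signal are flagged (``qc_fail``) and should be excluded from
    fitting — the signature of the acceptor-channel collapse that makes
    some receptor assays unfittable.
    """
    required = {"ligand", "conc_uM", "replicate", "em495", "em520", "role"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    bad_roles = set(plate["role"]) - WELL_ROLES
    if bad_roles:
        raise ValueError(f"unknown well roles: {sorted(bad_roles)}")
    if (plate["em495"] == 0).any() or (plate["em520"] == 0).any():
        raise ValueError("zero signal in an emission channel")
    df = plate.copy()
    if ratio == "520/495":
        df["ratio"] = df["em520"] / df["em495"]
    elif ratio == "495/520":
        df["ratio"] = df["em495"] / df["em520"]
    else:
        raise ValueError(f"unknown ratio direction: {ratio!r}")

    no_agonist = df[df["role"] == "no_agonist"]
    reference = df[df["role"] == "agonist_reference"]
    if no_agonist.empty or reference.empty:
        raise ValueError("plate lacks no-agonist or agonist-reference controls")
    r0 = no_agonist["ratio"].mean()
    top_conc = reference["conc_uM"].max()
    r100 = reference.loc[reference["conc_uM"] == top_conc, "ratio"].mean()
    if abs(r100 - r0) < 1e-12:
        raise ValueError("degenerate controls: 0% and 100% ratios coincide")
    df["response"] = 100.0 * (df["ratio"] - r0) / (r100 - r0)

    df["qc_fail"] = False
    no_lbd = df[df["role"] == "no_agonist_no_LBD"]
    if qc_acceptor_floor and not no_lbd.empty:
        floor = no_lbd["em520"].mean()
        mask = (df["role"] == "test") & (df["em520"] < floor)
        df.loc[mask, "qc_fail"] = True
    return df


def _4pl(logc: np.ndarray, lower: float, upper: float, log10_ec50: float,
         slope: float) -> np.ndarray:
    return lower + (upper - lower) / (1.0 + 10.0 ** (slope * (log10_ec50 - logc)))


def fit_4pl(conc: np.ndarray, response: np.ndarray,
            max_slope: float = 10.0) -> DoseResponseFit:
    """Least-squares 4PL fit on log10 concentration.

    Starting values come from response quartiles; the slope is bounded to
    ``(0, max_slope]`` and EC50 is parameterized as log10(EC50).  A flat
    response (no dynamic range beyond noise resolution) or a failed
    optimization returns a flagged fit with NaN EC50 rather than raising,
    so callers can branch on ``converged``.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if conc.shape != response.shape:
        raise ValueError("conc and response must have equal length")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if not np.all(np.isfinite(response)):
        raise ValueError("responses must be finite")
    if len(np.unique(conc)) < 5:
        raise ValueError("need at least 5 distinct concentrations")
    logc = np.log10(conc)

    spread = np.percentile(response, 97.5) - np.percentile(response, 2.5)
    if spread < 1e-9:
        return DoseResponseFit(
            lower=float(response.mean()), upper=float(response.mean()),
            ec50=float("nan"), slope=float("nan"), converged=False,
            n_points=len(conc),
        )

    q1, q3 = np.percentile(response, [25, 75])
    lo0 = float(np.min(response))
    hi0 = float(np.max(response))
    mid_mask = (response > q1) & (response < q3)
    ec0 = float(np.median(logc[mid_mask])) if mid_mask.any() else float(np.median(logc))
    p0 = [lo0, hi0, ec0, 1.0]
    bounds = (
        [-np.inf, -np.inf, logc.min() - 3.0, 1e-3],
        [np.inf, np.inf, logc.max() + 3.0, max_slope],
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                _4pl, logc, response, p0=p0, bounds=bounds, maxfev=20_000
            )
    except (RuntimeError, ValueError):
        return DoseResponseFit(
            lower=float("nan"), upper=float("nan"), ec50=float("nan"),
            slope=float("nan"), converged=False, n_points=len(conc),
        )
    if not np.all(np.isfinite(pcov)):
        return DoseResponseFit(
            lower=float(popt[0]), upper=float(popt[1]),
            ec50=float(10.0 ** popt[2]), slope=float(popt[3]),
            converged=False, n_points=len(conc),
        )
    perr = np.sqrt(np.diag(pcov))
    lower, upper, lec50, slope = (float(v) for v in popt)
    ec50 = 10.0 ** lec50
    se = {
        "lower": float(perr[0]),
        "upper": float(perr[1]),
        "log10_ec50": float(perr[2]),
        "slope": float(perr[3]),
        # delta method on EC50 = 10 ** log10(EC50)
        "ec50": float(np.log(10.0) * ec50 * perr[2]),
    }
    ci95 = {
        "lower": (lower - Z95 * se["lower"], lower + Z95 * se["lower"]),
        "upper": (upper - Z95 * se["upper"], upper + Z95 * se["upper"]),
        "ec50": (
            float(10.0 ** (lec50 - Z95 * se["log10_ec50"])),
            float(10.0 ** (lec50 + Z95 * se["log10_ec50"])),
        ),
        "slope": (slope - Z95 * se["slope"], slope + Z95 * se["slope"]),
    }
    return DoseResponseFit(
        lower=lower, upper=upper, ec50=float(ec50), slope=slope,
        se=se, ci95=ci95, converged=True,
        log10_ec50=lec50, se_log10_ec50=se["log10_ec50"], n_points=len(conc),
    )


def fit_plate(normalized: pd.DataFrame) -> dict[str, DoseResponseFit]:
    """Fit each ligand's pooled test wells (QC-failed wells excluded)."""
    fits = {}
    test = normalized[(normalized["role"] == "test") & (~normalized["qc_fail"])]
    for ligand, sub in test.groupby("ligand"):
        fits[str(ligand)] = fit_4pl(sub["conc_uM"].to_numpy(),
                                    sub["response"].to_numpy())
    return fits


def compare_parameters(fit_a: DoseResponseFit, fit_b: DoseResponseFit,
                       parameter: str) -> dict:
    """Wald z test for one 4PL parameter between two fitted ligands.

    ``z = (a - b) / sqrt(SE_a^2 + SE_b^2)`` with a two-sided normal p.
    ``parameter`` is one of ``lower``, ``upper`` (= E_max), ``ec50``,
    ``slope``.
    """
    if not (fit_a.converged and fit_b.converged):
        raise FitError("cannot compare parameters of a non-converged fit")
    valid = {"lower", "upper", "ec50", "slope"}
    if parameter not in valid:
        raise ValueError(f"parameter must be one of {sorted(valid)}")
    a, b = getattr(fit_a, parameter), getattr(fit_b, parameter)
    se_a, se_b = fit_a.se[parameter], fit_b.se[parameter]
    if not (np.isfinite(se_a) and np.isfinite(se_b)):
        raise FitError("non-finite standard error in comparison")
    pooled = float(np.hypot(se_a, se_b))
    if pooled == 0.0:
        z = 0.0 if a == b else float("inf")
    else:
        z = float((a - b) / pooled)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return {"parameter": parameter, "difference": float(a - b),
            "se": pooled, "z": z, "p_value": p}


def compare_table(fits: dict[str, DoseResponseFit], parameter: str,
                  alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise Wald comparisons plus a compact letter display."""
    from .pose_analysis import compact_letter_display

    names = sorted(fits)
    rows = []
    sig = set()
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = compare_parameters(fits[a], fits[b], parameter)
            res.update({"ligand_a": a, "ligand_b": b})
            rows.append(res)
            if res["p_value"] < alpha:
                sig.add((min(a, b), max(a, b)))
    letters = compact_letter_display(names, sig)
    out = pd.DataFrame(rows)
    out.attrs["letters"] = letters
    return out


def correlate_affinity(dg: np.ndarray, metric: np.ndarray,
                       method: str = "auto", alpha: float = 0.05) -> dict:
    """Correlate per-lipid predicted binding free energy with an assay metric.

    Pearson by default; falls back to Spearman when either vector fails a
    Shapiro-Wilk normality check (``method="auto"``).  Raises on constant
    input.
    """
    dg = np.asarray(dg, dtype=float)
    metric = np.asarray(metric, dtype=float)
    if dg.shape != metric.shape or len(dg) < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(dg) == 0 or np.std(metric) == 0:
        raise ValueError("zero variance in correlation input")
    chosen = method
    if method == "auto":
        normal = (
            stats.shapiro(dg).pvalue > alpha
            and stats.shapiro(metric).pvalue > alpha
        )
        chosen = "pearson" if normal else "spearman"
    if chosen == "pearson":
        r, p = stats.pearsonr(dg, metric)
    elif chosen == "spearman":
        r, p = stats.spearmanr(dg, metric)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return {"method": chosen, "r": float(r), "p_value": float(p), "n": len(dg)}
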