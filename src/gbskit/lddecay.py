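"""Linkage-disequilibrium decay with structure and kinship corrections.

Pairwise LD is the squared allele-frequency correlation r² between
inbred-line dosage vectors.  In panels with coancestry, raw r² between
unlinked loci is inflated; following the LDcorSV family of estimators
three corrected versions are provided:

* ``r²_s`` — structure-corrected: squared correlation of OLS residuals
  of both loci on scaled principal-component covariates;
* ``r²_v`` — kinship-corrected: squared (uncentred) correlation of
  ``K^{-1/2}(x - mu 1)`` with ``mu`` the GLS mean under covariance K;
* ``r²_sv`` — both: the same whitening applied to GLS residuals on the
  covariates.

Decay with map distance c (Morgans) is fit by nonlinear least squares
under two drift models, with C = 4 Ne c:

* Sved drift-recombination equilibrium:  E[r²] = 1 / (1 + C)
* Hill-Weir, with mutation and a sample-size (n) adjustment:
  E[r²] = [(10+C) / ((2+C)(11+C))] *
          [1 + ((3+C)(12+12C+C²)) / (n(2+C)(11+C))]

Each fit reports the effective population size Ne with its standard
error and the map distance at which the expected r² falls to 0.1 —
the marker-spacing requirement for association mapping.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .core import ConfigurationError, GeneticMap
from .structure import KinshipMatrix

LD_THRESHOLD = 0.1
MAX_PAIR_DISTANCE_CM = 30.0


# ---------------------------------------------------------------------------
# r-squared estimators
# ---------------------------------------------------------------------------

def r2_plain(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over lines complete at both loci."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        raise ConfigurationError("fewer than two complete pairs")
    xc = x[ok] - x[ok].mean()
    yc = y[ok] - y[ok].mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan")
    return float(((xc @ yc) / denom) ** 2)


def _inv_sqrt_psd(K: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    w, v = np.linalg.eigh(K)
    w = np.maximum(w, floor)
    return (v / np.sqrt(w)) @ v.T


@dataclass
class LDCorrector:
    """Precomputed transforms for corrected r² on a fixed panel.

    Parameters
    ----------
    S : DataFrame or None
        Structure covariates (lines x components, scaled to [0, 1]).
    K : KinshipMatrix or None
        Realized relatedness; a ridge of 1e-6 is added if needed to
        make it positive definite.
    """

    S: pd.DataFrame | None = None
    K: KinshipMatrix | None = None

    def __post_init__(self) -> None:
        self._T = None
        self._Kinv = None
        if self.K is not None:
            kv = self.K.values.to_numpy(float)
            w = np.linalg.eigvalsh(kv)
            if w.min() < 1e-10:
                kv = kv + 1e-6 * np.eye(kv.shape[0])
            self._T = _inv_sqrt_psd(kv)
            self._Kinv = self._T @ self._T

    def _design(self, n: int) -> np.ndarray:
        if self.S is None:
            return np.ones((n, 1))
        return np.column_stack([np.ones(n), self.S.to_numpy(float)])

    def _residual_ols(self, v: np.ndarray) -> np.ndarray:
        X = self._design(len(v))
        beta, *_ = np.linalg.lstsq(X, v, rcond=None)
        return v - X @ beta

    def _whitened_gls_residual(self, v: np.ndarray) -> np.ndarray:
        X = self._design(len(v))
        Ki = self._Kinv
        xtki = X.T @ Ki
        beta = np.linalg.pinv(xtki @ X) @ (xtki @ v)
        return self._T @ (v - X @ beta)

    def r2(self, x: np.ndarray, y: np.ndarray) -> float:
        """Corrected squared correlation; which correction applies is
        determined by the S and K supplied at construction."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if np.isnan(x).any() or np.isnan(y).any():
            raise ConfigurationError("corrected r2 requires complete data (impute first)")
        if self.K is None:
            if self.S is None:
                return r2_plain(x, y)
            u, v = self._residual_ols(x), self._residual_ols(y)
        else:
            u, v = self._whitened_gls_residual(x), self._whitened_gls_residual(y)
        denom = np.sqrt((u @ u) * (v @ v))
        if denom == 0:
            return float("nan")
        return float(((u @ v) / denom) ** 2)


def r2_corrected(
    x: np.ndarray,
    y: np.ndarray,
    S: pd.DataFrame | None = None,
    K: KinshipMatrix | None = None,
) -> float:
    """One-shot corrected r²; see :class:`LDCorrector`."""
    return LDCorrector(S=S, K=K).r2(x, y)


# ---------------------------------------------------------------------------
# pair distances across population maps
# ---------------------------------------------------------------------------

def pair_distances(
    pair: tuple[str, str],
    per_population_maps: Mapping[str, GeneticMap],
) -> tuple[float, float] | None:
    """Average and minimum map distance of a locus pair over populations.

    A population contributes only when both loci sit on the same
    linkage group of its map.  Returns None when never co-mapped.
    """
    a, b = pair
    dists = []
    for gmap in per_population_maps.values():
        t = gmap.table.set_index("locus")
        if a not in t.index or b not in t.index:
            continue
        ra, rb = t.loc[a], t.loc[b]
        if ra["linkage_group"] != rb["linkage_group"]:
            continue
        dists.append(abs(float(ra["position_cm"]) - float(rb["position_cm"])))
    if not dists:
        return None
    return float(np.mean(dists)), float(np.min(dists))


def build_ld_records(
    X: pd.DataFrame,
    per_population_maps: Mapping[str, GeneticMap],
    correctors: Mapping[str, LDCorrector],
    max_distance_cm: float = MAX_PAIR_DISTANCE_CM,
) -> pd.DataFrame:
    """LD records for all locus pairs co-mapped within the distance cap.

    ``X`` is a lines x loci dosage matrix (complete; impute upstream),
    ``correctors`` maps estimator names (e.g. 'r2', 'r2_v') to
    :class:`LDCorrector` instances.  Pairs with undefined r² (zero
    variance) are dropped.
    """
    cols = list(X.columns)
    rows = []
    arr = X.to_numpy(float)
    idx = {c: i for i, c in enumerate(cols)}
    for a, b in itertools.combinations(cols, 2):
        d = pair_distances((a, b), per_population_maps)
        if d is None:
            continue
        avg_d, min_d = d
        if min(avg_d, min_d) > max_distance_cm:
            continue
        rec = {"locusA": a, "locusB": b, "avg_cm": avg_d, "min_cm": min_d}
        ok = True
        for name, corr in correctors.items():
            v = corr.r2(arr[:, idx[a]], arr[:, idx[b]])
            if np.isnan(v):
                ok = False
                break
            rec[name] = v
        if ok:
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# decay models
# ---------------------------------------------------------------------------

def sved_expectation(c_morgans: np.ndarray, ne: float) -> np.ndarray:
    """Drift-recombination equilibrium: E[r²] = 1/(1 + 4 Ne c)."""
    return 1.0 / (1.0 + 4.0 * ne * np.asarray(c_morgans, float))


def hillweir_expectation(c_morgans: np.ndarray, ne: float, n: int) -> np.ndarray:
    """Hill-Weir drift expectation with mutation and sample-size n."""
    C = 4.0 * ne * np.asarray(c_morgans, float)
    lead = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    adj = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (
        n * (2.0 + C) * (11.0 + C)
    )
    return lead * adj


@dataclass
class LDModelFit:
    """Fitted LD-decay model.

    ``d01_cm`` is the map distance at which the fitted expectation
    crosses ``LD_THRESHOLD`` (0.1) — the marker spacing needed for
    association scans.
    """

    model: str
    ne: float
    ne_se: float
    n: int | None
    d01_cm: float

    def summary_row(self) -> dict:
        return {
            "model": self.model,
            "Ne": self.ne,
            "Ne_se": self.ne_se,
            "d01_cm": self.d01_cm,
        }


def sved_d01_cm(ne: float) -> float:
    """Closed form: 1/(1+4 Ne c) = 0.1  =>  c = 9/(4 Ne) Morgans."""
    if ne <= 0:
        raise ConfigurationError("Ne must be positive")
    return 100.0 * 9.0 / (4.0 * ne)


def hillweir_d01_cm(ne: float, n: int, threshold: float = LD_THRESHOLD) -> float:
    """Distance where the Hill-Weir expectation equals the threshold,
    by numerical root-solve in C = 4 Ne c."""
    if ne <= 0:
        raise ConfigurationError("Ne must be positive")

    def f(C: float) -> float:
        return float(hillweir_expectation(C / (4.0 * ne), ne, n) - threshold)

    c_star = optimize.brentq(f, 1e-9, 1e9)
    return 100.0 * c_star / (4.0 * ne)


def _fit(
    records: pd.DataFrame,
    distance_field: str,
    model: str,
    n: int | None,
    r2_field: str,
    p0: float,
) -> LDModelFit:
    use = records[records[distance_field] <= MAX_PAIR_DISTANCE_CM]
    if len(use) < 10:
        raise ConfigurationError(
            f"need >= 10 records within {MAX_PAIR_DISTANCE_CM} cM, got {len(use)}"
        )
    c = use[distance_field].to_numpy(float) / 100.0  # cM -> Morgans
    y = use[r2_field].to_numpy(float)
    if model == "sved":
        fun = lambda cc, ne: sved_expectation(cc, ne)
    else:
        fun = lambda cc, ne: hillweir_expectation(cc, ne, n)
    try:
        popt, pcov = optimize.curve_fit(
            fun, c, y, p0=[p0], bounds=(1e-6, 1e7), maxfev=10000
        )
    except RuntimeError as exc:
        raise ConfigurationError(f"{model} fit did not converge: {exc}") from exc
    ne = float(popt[0])
    ne_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    d01 = sved_d01_cm(ne) if model == "sved" else hillweir_d01_cm(ne, n)
    return LDModelFit(model=model, ne=ne, ne_se=ne_se, n=n, d01_cm=d01)


def fit_sved(
    records: pd.DataFrame,
    distance_field: str = "avg_cm",
    r2_field: str = "r2",
    p0: float = 50.0,
) -> LDModelFit:
    """Fit the Sved model by unweighted nonlinear least squares."""
    return _fit(records, distance_field, "sved", None, r2_field, p0)


def fit_hillweir(
    records: pd.DataFrame,
    n: int,
    distance_field: str = "avg_cm",
    r2_field: str = "r2",
    p0: float = 50.0,
) -> LDModelFit:
    """Fit the Hill-Weir model (sample size ``n`` = number of inbred
    lines in the panel) by unweighted nonlinear least squares."""
    return _fit(records, distance_field, "hillweir", n, r2_field, p0)


def decay_summary(
    records: pd.DataFrame,
    n: int,
    estimators: Sequence[str] = ("r2", "r2_s", "r2_v", "r2_sv"),
    distance_fields: Sequence[str] = ("avg_cm", "min_cm"),
) -> pd.DataFrame:
    """Fit both models for every estimator x distance-type combination;
    one row per fit (estimator, model, distance, Ne, Ne_se, d01_cm)."""
    rows = []
    for est in estimators:
        if est not in records.columns:
            continue
        for dist in distance_fields:
            for model in ("hillweir", "sved"):
                fit = (
                    fit_hillweir(records, n, dist, est)
                    if model == "hillweir"
                    else fit_sved(records, dist, est)
                )
                rows.append(
                    {
                        "estimator": est,
                        "distance": dist,
                        "model": model,
                        "Ne": fit.ne,
                        "Ne_se": fit.ne_se,
                        "d01_cm": fit.d01_cm,
                    }
                )
    return pd.DataFrame(rows)
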