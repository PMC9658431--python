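"""Path analysis of evapotranspiration against meteorological drivers.

Path analysis decomposes each driver's correlation with ET into a direct
effect (its standardized multiple-regression coefficient P) and indirect
effects routed through the other, correlated drivers (r_ij·P_j).  The
decision coefficient Rd = 2·P·r − P² summarizes a driver's total
determinative contribution.  For exactly multivariate data the identity
r_i = P_i + Σ_{j≠i} r_ij·P_j holds; the residual of that identity is
reported per driver rather than forced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PathTable",
    "standardize",
    "direct_path_coefficients",
    "indirect_path_coefficients",
    "decision_coefficients",
    "path_analysis",
]

DEFAULT_DRIVERS = ("Rn", "Ta", "VPD", "u2")
#: Hour range (inclusive on both ends) of the greenhouse ventilation period.
DEFAULT_WINDOW = (9, 16)


@dataclass(frozen=True)
class PathTable:
    """Full path-analysis decomposition for one driver set.

    Attributes
    ----------
    drivers : tuple of str
    r : Series
        Correlation of each driver with the response.
    direct : Series
        Direct path coefficients (standardized OLS).
    indirect : DataFrame
        Entry (i, j) = r_ij·P_j, the indirect path of driver i through
        driver j; the diagonal is empty (NaN).
    total_indirect : Series
        Row sums of ``indirect`` excluding the diagonal.
    decision : Series
        Decision coefficients Rd = 2·P·r − P².
    residual : Series
        r_i − (P_i + total_indirect_i), the path-identity residual.
    n : int
        Number of observations used.
    """

    drivers: tuple
    r: pd.Series
    direct: pd.Series
    indirect: pd.DataFrame
    total_indirect: pd.Series
    decision: pd.Series
    residual: pd.Series
    n: int

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one row per driver, Table-style column order."""
        out = pd.DataFrame(
            {
                "correlation": self.r,
                "direct": self.direct,
                "total_indirect": self.total_indirect,
            }
        )
        for d in self.drivers:
            out[f"via_{d}"] = self.indirect[d]
        out["decision"] = self.decision
        out["residual"] = self.residual
        return out

    def to_text(self) -> str:
        """Aligned plain-text rendering of :meth:`to_frame`."""
        return self.to_frame().round(3).to_string()


def standardize(values, name: str = "series"):
    """Zero-mean, unit-variance (n−1 denominator) standardization."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"cannot standardize zero-variance variable '{name}'")
    return (x - x.mean()) / sd


def direct_path_coefficients(X: pd.DataFrame, y) -> pd.Series:
    """Direct path coefficients: standardized OLS via the normal equations.

    P solves R_xx·P = r_xy, where R_xx is the driver correlation matrix
    and r_xy the driver–response correlations.
    """
    if len(X) <= X.shape[1]:
        raise ValueError("need more observations than drivers")
    Z = np.column_stack([standardize(X[c], c) for c in X.columns])
    zy = standardize(np.asarray(y, dtype=float), "response")
    n = len(zy)
    Rxx = Z.T @ Z / (n - 1)
    rxy = Z.T @ zy / (n - 1)
    try:
        P = np.linalg.solve(Rxx, rxy)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular driver correlation matrix — drivers are collinear; "
            "drop one of the correlated drivers"
        ) from exc
    return pd.Series(P, index=X.columns, name="direct")


def indirect_path_coefficients(
    Rxx: pd.DataFrame, P: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Indirect paths (i via j) = r_ij·P_j and their row totals.

    The diagonal (a driver via itself) is left empty.
    """
    Rxx = pd.DataFrame(Rxx)
    indirect = Rxx.mul(P, axis="columns")
    np.fill_diagonal(indirect.values, np.nan)
    totals = indirect.sum(axis=1, skipna=True).rename("total_indirect")
    return indirect, totals


def decision_coefficients(P, r):
    """Decision coefficients Rd = 2·P·r − P² (per driver)."""
    P = np.asarray(P, dtype=float)
    r = np.asarray(r, dtype=float)
    out = 2.0 * P * r - P**2
    return float(out) if out.ndim == 0 else out


def path_analysis(
    table: pd.DataFrame,
    response: str = "ET",
    drivers=DEFAULT_DRIVERS,
    window: tuple[int, int] | None = DEFAULT_WINDOW,
) -> PathTable:
    """Path-analysis decomposition of hourly ET against its drivers.

    Parameters
    ----------
    table : DataFrame
        Hourly records indexed by timestamp, containing the response and
        every driver column.
    window : (start_hour, end_hour), optional
        Keep only rows whose hour lies in the window, inclusive on both
        ends (the default 9–16 keeps 8 hourly rows per day — the
        greenhouse ventilation period).  ``None`` keeps all rows.
    """
    drivers = tuple(drivers)
    missing = [c for c in (*drivers, response) if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if window is not None:
        lo, hi = window
        if lo > hi:
            raise ValueError("window start must not exceed end")
        hours = pd.DatetimeIndex(table.index).hour
        table = table[(hours >= lo) & (hours <= hi)]
    table = table.dropna(subset=[*drivers, response])
    if len(table) < len(drivers) + 1:
        raise ValueError(
            f"only {len(table)} rows after window filtering; "
            f"need at least {len(drivers) + 1}"
        )

    X = table[list(drivers)]
    y = table[response].to_numpy(dtype=float)
    P = direct_path_coefficients(X, y)

    Z = np.column_stack([standardize(X[c], c) for c in drivers])
    zy = standardize(y, response)
    n = len(zy)
    Rxx = pd.DataFrame(Z.T @ Z / (n - 1), index=drivers, columns=drivers)
    r = pd.Series(Z.T @ zy / (n - 1), index=drivers, name="correlation")

    indirect, totals = indirect_path_coefficients(Rxx, P)
    Rd = pd.Series(decision_coefficients(P, r), index=P.index, name="decision")
    residual = (r - (P + totals)).rename("residual")
    return PathTable(
        drivers=drivers,
        r=r,
        direct=P,
        indirect=indirect,
        total_indirect=totals,
        decision=Rd,
        residual=residual,
        n=n,
    )
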