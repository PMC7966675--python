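"""Mortality monetisation (VSL) and input–output economic-loss propagation.

Direct losses are first-order losses of labour capacity (or output) in the
shocked sector; indirect losses are the higher-order losses transmitted to
other sectors through inter-industry dependencies, obtained from the
Leontief inverse L = (I − A)^{-1}.  Losses are reported both in gross-output
and in value-added (GDP) terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IOTable",
    "VSLConfig",
    "EconomicLossResult",
    "EconomyError",
    "monetise_mortality",
    "leontief_inverse",
    "io_losses",
]

#: value of a statistical life for China, 2015 USD
DEFAULT_VSL = 3.2e6


class EconomyError(ValueError):
    """The economy is not productive (spectral radius >= 1) or inconsistent."""


@dataclass(frozen=True)
class VSLConfig:
    """Value of a statistical life, on a 2015-USD basis."""

    vsl: float = DEFAULT_VSL

    def __post_init__(self) -> None:
        if self.vsl <= 0:
            raise ValueError("VSL must be positive")


@dataclass
class IOTable:
    """Square input–output table: coefficients A, output x, value added, final demand.

    Invariants checked on construction: spectral radius of A < 1 (productive
    economy), the accounting identity x = A·x + f to 1e-6 relative
    tolerance, and value-added coefficients v = VA/x in (0, 1].
    """

    coefficients: np.ndarray
    gross_output: np.ndarray
    value_added: np.ndarray
    final_demand: np.ndarray
    workers: np.ndarray | None = None
    sectors: list = field(default_factory=list)

    def __post_init__(self) -> None:
        A = np.asarray(self.coefficients, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"coefficient matrix must be square, got {A.shape}")
        self.coefficients = A
        k = A.shape[0]
        for name in ("gross_output", "value_added", "final_demand"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (k,):
                raise ValueError(f"{name} must have shape ({k},), got {v.shape}")
            setattr(self, name, v)
        if self.workers is not None:
            self.workers = np.asarray(self.workers, dtype=float)
        if not self.sectors:
            self.sectors = [f"sector_{i}" for i in range(k)]

        rho = self.spectral_radius
        if rho >= 1.0:
            raise EconomyError(
                f"economy not productive: spectral radius {rho:.6f} >= 1"
            )
        resid = self.gross_output - (A @ self.gross_output + self.final_demand)
        scale = np.maximum(np.abs(self.gross_output), 1.0)
        if np.any(np.abs(resid) / scale > 1e-6):
            raise EconomyError(
                "accounting identity x = A·x + f violated beyond 1e-6 relative tolerance"
            )
        v = self.value_added_coefficients
        if np.any(v <= 0) or np.any(v > 1 + 1e-9):
            raise EconomyError("value-added coefficients must lie in (0, 1]")

    @property
    def n_sectors(self) -> int:
        return self.coefficients.shape[0]

    @property
    def spectral_radius(self) -> float:
        return float(max(abs(np.linalg.eigvals(self.coefficients))))

    @property
    def value_added_coefficients(self) -> np.ndarray:
        return self.value_added / self.gross_output

    @property
    def gdp(self) -> float:
        return float(self.value_added.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coefficients, index=self.sectors, columns=self.sectors)
        df["gross_output"] = self.gross_output
        df["value_added"] = self.value_added
        df["final_demand"] = self.final_demand
        if self.workers is not None:
            df["workers"] = self.workers
        return df


@dataclass
class EconomicLossResult:
    """Per-sector and total direct/indirect/total losses, in output and VA terms."""

    sectors: list
    direct_output: np.ndarray
    indirect_output: np.ndarray
    direct_va: np.ndarray
    indirect_va: np.ndarray
    gdp: float

    @property
    def total_output(self) -> np.ndarray:
        return self.direct_output + self.indirect_output

    @property
    def total_va(self) -> np.ndarray:
        return self.direct_va + self.indirect_va

    @property
    def total_loss(self) -> float:
        """Economy-wide loss in value-added (GDP) terms."""
        return float(self.total_va.sum())

    @property
    def gdp_share_pct(self) -> float:
        return 100.0 * self.total_loss / self.gdp

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sector": self.sectors,
                "direct_output_loss": self.direct_output,
                "indirect_output_loss": self.indirect_output,
                "total_output_loss": self.total_output,
                "direct_va_loss": self.direct_va,
                "indirect_va_loss": self.indirect_va,
                "total_va_loss": self.total_va,
            }
        )


def monetise_mortality(
    deaths: float | np.ndarray,
    vsl: VSLConfig | float = DEFAULT_VSL,
    gdp: float | None = None,
):
    """Monetise premature deaths at the value of a statistical life.

    Returns the cost (same shape as ``deaths``); if ``gdp`` is supplied,
    returns ``(cost, gdp_share_pct)``.
    """
    d = np.asarray(deaths, dtype=float)
    if np.any(d < 0):
        raise ValueError("deaths must be nonnegative")
    v = vsl.vsl if isinstance(vsl, VSLConfig) else float(vsl)
    if v <= 0:
        raise ValueError("VSL must be positive")
    cost = d * v
    cost = cost.item() if np.isscalar(deaths) or np.ndim(deaths) == 0 else cost
    if gdp is not None:
        return cost, 100.0 * np.sum(cost) / gdp
    return cost


def leontief_inverse(A: np.ndarray) -> np.ndarray:
    """Leontief inverse L = (I − A)^{-1}.

    Requires a productive economy (spectral radius of A strictly below 1);
    for nonnegative A, L >= I componentwise.
    """
    A = np.asarray(A, dtype=float)
    rho = float(max(abs(np.linalg.eigvals(A))))
    if rho >= 1.0:
        raise EconomyError(f"economy not productive: spectral radius {rho:.6f} >= 1")
    eye = np.eye(A.shape[0])
    return np.linalg.solve(eye - A, eye)


def _ghosh_inverse(io: IOTable) -> np.ndarray:
    # allocation (output) coefficients B_ij = Z_ij / x_i, Z = A diag(x)
    Z = io.coefficients * io.gross_output[None, :]
    B = Z / io.gross_output[:, None]
    rho = float(max(abs(np.linalg.eigvals(B))))
    if rho >= 1.0:
        raise EconomyError(f"Ghosh system not productive: spectral radius {rho:.6f}")
    eye = np.eye(B.shape[0])
    return np.linalg.solve(eye - B.T, eye)


def io_losses(
    shock: np.ndarray,
    io: IOTable,
    shock_kind: str = "labour-share",
    method: str = "leontief",
    va_per_worker_year: float | None = None,
) -> EconomicLossResult:
    """Propagate a direct sectoral shock through the inter-industry structure.

    Parameters
    ----------
    shock : per-sector direct shock.  Interpretation depends on ``shock_kind``:
        - ``labour-share``: fraction of each sector's labour (hence output)
          lost, in [0, 1]; direct output loss is share × gross output.
        - ``output``: direct output loss in currency, taken as given.
        - ``deaths-to-labour``: premature deaths per sector, converted to
          lost worker-years valued at per-worker value added
          (``va_per_worker_year`` or VA/workers from the table).
    io : the input–output table.
    method : ``leontief`` (demand-side, default) or ``ghosh`` (supply-side).

    The direct loss vector is propagated as a demand-equivalent withdrawal:
    total output loss Δx_t = L·Δx_d, indirect = Δx_t − Δx_d.  Value-added
    losses apply the coefficients v = VA/x to the output losses.
    """
    s = np.asarray(shock, dtype=float)
    if s.shape != (io.n_sectors,):
        raise ValueError(f"shock must have shape ({io.n_sectors},), got {s.shape}")
    if np.any(s < 0):
        raise ValueError("shocks must be nonnegative")

    if shock_kind == "labour-share":
        if np.any(s > 1):
            raise ValueError("labour-share shocks must be <= 1")
        direct = s * io.gross_output
    elif shock_kind == "output":
        direct = s
    elif shock_kind == "deaths-to-labour":
        if va_per_worker_year is None:
            if io.workers is None:
                raise ValueError(
                    "deaths-to-labour shock needs va_per_worker_year or a workers column"
                )
            per_worker = io.value_added / io.workers
        else:
            per_worker = np.full(io.n_sectors, float(va_per_worker_year))
        # deaths -> lost worker-years of value added -> output equivalent via v
        direct = s * per_worker / io.value_added_coefficients
    else:
        raise ValueError(f"unknown shock_kind {shock_kind!r}")

    if method == "leontief":
        total = leontief_inverse(io.coefficients) @ direct
    elif method == "ghosh":
        total = _ghosh_inverse(io) @ direct
    else:
        raise ValueError(f"unknown method {method!r}")

    indirect = total - direct
    v = io.value_added_coefficients
    return EconomicLossResult(
        sectors=list(io.sectors),
        direct_output=direct,
        indirect_output=indirect,
        direct_va=v * direct,
        indirect_va=v * indirect,
        gdp=io.gdp,
    )
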