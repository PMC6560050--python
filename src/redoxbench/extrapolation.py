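"""Complete-basis-set (CBS) extrapolation of HF and correlation energies.

Two schemes are implemented, both operating on per-species absolute
energies whose HF and correlation components are extrapolated separately:

* **Scheme I** (two-point power law, DZ/TZ): assumes
  ``E(X) = E_CBS + A * X**(-p)`` with p = alpha = 4.93 for the HF component
  and p = beta = 2.13 for the correlation component. The CBS limit follows
  in closed form from two cardinals.
* **Scheme II** (TZ/QZ correlation, three-point HF): the correlation
  component uses the same two-point power law with the canonical exponent
  p = 3 on the TZ/QZ pair; the HF component is fit to
  ``E(X) = E_CBS + A * exp(-B*X)`` through the DZ/TZ/QZ triple and solved
  in closed form (Aitken delta-squared), which is exact when the series is
  exactly exponential.

Both two-point formulas are fixed linear combinations of the inputs, so
extrapolating a difference of series equals the difference of the
extrapolations; the three-point exponential fit is nonlinear and enjoys no
such property.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .model import BasisLevel, ComponentEnergy
from .units import Quantity

#: Literature exponents for the scheme I power-law extrapolation.
DEFAULT_ALPHA = 4.93
DEFAULT_BETA = 2.13

#: Canonical inverse-cube exponent for correlation-energy extrapolation.
CORRELATION_CUBE_EXPONENT = 3.0


class Scheme(str, enum.Enum):
    SCHEME1 = "scheme1"
    SCHEME2 = "scheme2"


class HfCbsMode(str, enum.Enum):
    """How scheme II treats the HF component (two defensible readings)."""

    EXPONENTIAL = "exponential"  # three-point exponential fit (default)
    EQ2 = "eq2"                  # same two-point power law as scheme I


class ExtrapolationError(ValueError):
    """Input series violates the assumptions of the requested fit."""


@dataclass(frozen=True)
class ExtrapolationParams:
    """Power-law exponents for the two-point scheme.

    alpha applies to the HF component, beta to correlation.
    """

    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    hf_cbs_mode: HfCbsMode = HfCbsMode.EXPONENTIAL

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("extrapolation exponents must be positive")
        if not isinstance(self.hf_cbs_mode, HfCbsMode):
            object.__setattr__(self, "hf_cbs_mode", HfCbsMode(self.hf_cbs_mode))


@dataclass(frozen=True)
class CbsResult:
    """An extrapolated CBS energy with its provenance."""

    cbs_hf: Quantity
    cbs_corr: Quantity
    scheme: Scheme
    inputs_used: tuple[tuple[BasisLevel, ComponentEnergy], ...] = field(
        default=(), compare=False
    )

    @property
    def cbs_total(self) -> Quantity:
        return self.cbs_hf + self.cbs_corr


def two_point_power_cbs(e_lo: Quantity, e_hi: Quantity,
                        x_lo: int, x_hi: int, exponent: float) -> Quantity:
    """Two-point CBS limit under ``E(X) = E_CBS + A * X**(-p)``.

    Returns ``(x_hi**p * e_hi - x_lo**p * e_lo) / (x_hi**p - x_lo**p)``,
    the exact fixed point of the assumed power-law decay. The two
    coefficients sum to one, so a constant series is its own limit.
    """
    if x_lo < 2 or x_hi <= x_lo:
        raise ExtrapolationError(
            f"need x_hi > x_lo >= 2, got x_lo={x_lo}, x_hi={x_hi}"
        )
    if exponent <= 0:
        raise ExtrapolationError(f"exponent must be positive, got {exponent}")
    w_hi = x_hi ** exponent
    w_lo = x_lo ** exponent
    # weights (w_hi, -w_lo) / (w_hi - w_lo) sum to exactly 1
    return (e_hi * w_hi - e_lo * w_lo) / (w_hi - w_lo)


def hf_exponential_cbs(e_dz: Quantity, e_tz: Quantity,
                       e_qz: Quantity) -> Quantity:
    """Three-point CBS limit under ``E(X) = E_CBS + A * exp(-B*X)``.

    With consecutive cardinals the geometric decay makes the closed-form
    solution the Aitken delta-squared limit ``e_qz - d2**2 / (d1 - d2)``
    where ``d1 = e_dz - e_tz`` and ``d2 = e_tz - e_qz``. Exact when the
    series is exactly exponential. The series must be monotone and
    contracting (d1*d2 > 0 and |d2| < |d1|); anything else has no
    exponential interpolant with B > 0.
    """
    d1 = (e_dz - e_tz).value
    d2 = (e_tz - e_qz).value
    if d1 * d2 <= 0:
        raise ExtrapolationError(
            "HF series is not monotone: successive differences "
            f"d1={d1:.6g}, d2={d2:.6g} do not share a sign"
        )
    # the relative guard also catches linear decay (d1 == d2 up to round-off),
    # where the denominator vanishes and no B > 0 interpolant exists
    if abs(d2) >= abs(d1) or abs(d1 - d2) <= 1e-9 * max(abs(d1), abs(d2)):
        raise ExtrapolationError(
            "HF series is not contracting: |d2| must be < |d1|, got "
            f"d1={d1:.6g}, d2={d2:.6g}"
        )
    return e_qz - Quantity(d2 * d2 / (d1 - d2), e_qz.unit)


def scheme1_cbs(e_dz: ComponentEnergy, e_tz: ComponentEnergy,
                params: ExtrapolationParams | None = None) -> CbsResult:
    """Scheme I: two-point DZ/TZ power-law extrapolation.

    HF uses exponent alpha, correlation exponent beta.
    """
    params = params or ExtrapolationParams()
    cbs_hf = two_point_power_cbs(e_dz.hf, e_tz.hf, 2, 3, params.alpha)
    cbs_corr = two_point_power_cbs(e_dz.corr, e_tz.corr, 2, 3, params.beta)
    return CbsResult(
        cbs_hf=cbs_hf,
        cbs_corr=cbs_corr,
        scheme=Scheme.SCHEME1,
        inputs_used=((BasisLevel(2), e_dz), (BasisLevel(3), e_tz)),
    )


def scheme2_cbs(e_dz: ComponentEnergy, e_tz: ComponentEnergy,
                e_qz: ComponentEnergy,
                params: ExtrapolationParams | None = None) -> CbsResult:
    """Scheme II: TZ/QZ inverse-cube correlation; three-point exponential HF.

    ``params.hf_cbs_mode`` selects the HF treatment: the default
    ``exponential`` fits the DZ/TZ/QZ triple; ``eq2`` reuses the scheme I
    two-point power law (exponent alpha) on DZ/TZ.
    """
    params = params or ExtrapolationParams()
    cbs_corr = two_point_power_cbs(
        e_tz.corr, e_qz.corr, 3, 4, CORRELATION_CUBE_EXPONENT
    )
    if params.hf_cbs_mode is HfCbsMode.EXPONENTIAL:
        cbs_hf = hf_exponential_cbs(e_dz.hf, e_tz.hf, e_qz.hf)
    else:
        cbs_hf = two_point_power_cbs(e_dz.hf, e_tz.hf, 2, 3, params.alpha)
    return CbsResult(
        cbs_hf=cbs_hf,
        cbs_corr=cbs_corr,
        scheme=Scheme.SCHEME2,
        inputs_used=(
            (BasisLevel(2), e_dz), (BasisLevel(3), e_tz), (BasisLevel(4), e_qz)
        ),
    )
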