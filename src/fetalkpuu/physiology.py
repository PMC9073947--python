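"""Gestational-age-dependent physiology.

Every quantity in this module is a scale factor or size indexed by
gestational week (GW): placental volume, pregnancy-induced hepatic CYP450
activity multipliers, and the relative abundance of the placental efflux
transporters P-gp and BCRP (apical, maternal-facing membrane of the
syncytiotrophoblast) expressed relative to their term value.

Trimesters follow the HHS partition: weeks 1-12 first, 13-28 second,
29-40 third. Gestational week 0 denotes the nonpregnant / postpartum
reference state, for which every multiplier is exactly 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GestationalWeek",
    "CypActivityTable",
    "TransporterAbundanceCurve",
    "DEFAULT_CYP_TABLE",
    "placental_volume",
    "cyp_multiplier",
    "relative_abundance",
    "default_abundance_curve",
]

GW_MAX = 42.0


@dataclass(frozen=True)
class GestationalWeek:
    """Gestational age in weeks; 0 means nonpregnant/postpartum."""

    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= GW_MAX:
            raise ValueError(
                f"gestational week must be in [0, {GW_MAX}], got {self.value}"
            )

    @property
    def trimester(self) -> str:
        """HHS trimester label: 1-12 first, 13-28 second, 29-40 third."""
        v = self.value
        if v == 0:
            return "nonpregnant"
        if v <= 12:
            return "first"
        if v <= 28:
            return "second"
        return "third"

    def __float__(self) -> float:
        return float(self.value)


def _as_gw(gw: "GestationalWeek | float") -> GestationalWeek:
    return gw if isinstance(gw, GestationalWeek) else GestationalWeek(float(gw))


# ---------------------------------------------------------------------------
# Hepatic CYP450 activity in pregnancy
# ---------------------------------------------------------------------------

#: Fold-change in hepatic CYP activity vs the nonpregnant state, by trimester.
#: Suppressions are stored as the residual fraction (e.g. CYP1A2 suppressed by
#: 65% in the third trimester -> 0.35). First-trimester changes are not
#: characterised for these isoforms and default to the nonpregnant value.
#: CYP2E1 has no reported pregnancy change and defaults to 1.0.
_DEFAULT_MULTIPLIERS: dict[str, tuple[float, float]] = {
    # isoform: (second trimester, third trimester)
    "CYP3A": (2.0, 2.0),
    "CYP2D6": (1.9, 2.0),
    "CYP1A2": (1 - 0.48, 1 - 0.65),
    "CYP2B6": (1.1, 1.3),
    "CYP2C9": (1.5, 1.6),
    "CYP2C19": (1 - 0.62, 1 - 0.68),
    "CYP2E1": (1.0, 1.0),
}


@dataclass(frozen=True)
class CypActivityTable:
    """Per-isoform hepatic activity multipliers by trimester.

    The nonpregnant (and, by assumption, first-trimester and postpartum)
    column is identically 1.0 and is therefore not stored.
    """

    multipliers: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_MULTIPLIERS)
    )

    def __post_init__(self) -> None:
        for iso, (t2, t3) in self.multipliers.items():
            if t2 <= 0 or t3 <= 0:
                raise ValueError(f"multiplier for {iso} must be strictly positive")

    @property
    def isoforms(self) -> frozenset[str]:
        return frozenset(self.multipliers)

    def multiplier(self, isoform: str, gw: "GestationalWeek | float") -> float:
        """Activity fold-change for ``isoform`` at gestational week ``gw``.

        Raises
        ------
        KeyError
            If the isoform is not in the table.
        """
        if isoform not in self.multipliers:
            raise KeyError(
                f"unknown CYP isoform {isoform!r}; known: {sorted(self.multipliers)}"
            )
        tri = _as_gw(gw).trimester
        if tri in ("nonpregnant", "first"):
            return 1.0
        t2, t3 = self.multipliers[isoform]
        return t2 if tri == "second" else t3


DEFAULT_CYP_TABLE = CypActivityTable()


def cyp_multiplier(
    isoform: str,
    gw: "GestationalWeek | float",
    table: CypActivityTable = DEFAULT_CYP_TABLE,
) -> float:
    """Pregnancy fold-change in hepatic activity of one CYP isoform."""
    return table.multiplier(isoform, gw)


# ---------------------------------------------------------------------------
# Placental volume
# ---------------------------------------------------------------------------

# Quadratic growth curve V(GW) = a*GW + b*GW^2 (ml), zero at conception,
# calibrated so that V(38) = 624 ml — the volume at which the
# midazolam-calibrated passive-diffusion clearance of nelfinavir
# (500 * 8.8 / 489.9 = 8.98 l/h) converts to the intrinsic per-ml value of
# 240 ul/min/ml — and V(25) = 300 ml, a mid-second/third-trimester size
# consistent with sonographic growth curves.
_PLACENTA_A = 3.49798
_PLACENTA_B = 0.34008


def placental_volume(
    gw: "GestationalWeek | float",
    coefficients: tuple[float, float] = (_PLACENTA_A, _PLACENTA_B),
) -> float:
    """Placental volume in ml at gestational week ``gw``.

    Strictly positive and monotonically increasing for 0 < GW <= 42.
    GW 0 is a domain error: there is no placenta in the reference state.
    """
    g = float(_as_gw(gw))
    if g <= 0:
        raise ValueError("placental volume is undefined at gestational week 0")
    a, b = coefficients
    vol = a * g + b * g * g
    if vol <= 0:
        raise ValueError(f"coefficients {coefficients} give nonpositive volume at GW {g}")
    return vol


# ---------------------------------------------------------------------------
# Placental transporter abundance vs gestational age
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransporterAbundanceCurve:
    """Second-order polynomial in GW for placental transporter abundance
    relative to the term value (term ≡ 1.0).

    The default curves shipped by :func:`default_abundance_curve` are anchored
    so that, combined with the term clearance estimates, the steady-state
    unbound ratio reproduces the published gestational trajectory; they stand
    in for the underlying proteomic abundance data, which are not public.
    Evaluation outside ``gw_range`` is a domain error — the quadratic is an
    interpolant, not an extrapolation model.
    """

    transporter: str  # "P-gp" | "BCRP"
    coefficients: tuple[float, float, float]  # c0 + c1*GW + c2*GW^2
    gw_range: tuple[float, float]
    term_gw: float

    def __post_init__(self) -> None:
        lo, hi = self.gw_range
        if not lo < hi:
            raise ValueError("gw_range must be increasing")
        if not lo <= self.term_gw <= hi:
            raise ValueError("term_gw must lie inside gw_range")
        if abs(self._eval(self.term_gw) - 1.0) > 1e-6:
            raise ValueError("abundance curve must equal 1.0 at term")
        grid = np.linspace(lo, hi, 200)
        if np.any(self._eval(grid) <= 0):
            raise ValueError("abundance curve must be positive over its valid range")

    def _eval(self, gw):
        c0, c1, c2 = self.coefficients
        return c0 + c1 * np.asarray(gw, dtype=float) + c2 * np.asarray(gw, dtype=float) ** 2

    def __call__(self, gw: "GestationalWeek | float") -> float:
        g = float(_as_gw(gw))
        lo, hi = self.gw_range
        if not lo <= g <= hi:
            raise ValueError(
                f"GW {g} outside the fitted range [{lo}, {hi}] of the "
                f"{self.transporter} abundance curve (no extrapolation)"
            )
        return float(self._eval(g))

    @classmethod
    def from_anchors(
        cls,
        transporter: str,
        anchors: dict[float, float],
        term_gw: float,
        gw_range: tuple[float, float] | None = None,
    ) -> "TransporterAbundanceCurve":
        """Fit the quadratic exactly through three (GW, relative abundance)
        anchor points; one anchor must be (term_gw, 1.0)."""
        pts = dict(anchors)
        pts.setdefault(term_gw, 1.0)
        if len(pts) != 3:
            raise ValueError("exactly three anchor points are required")
        gws = np.array(sorted(pts))
        vals = np.array([pts[g] for g in gws])
        coeffs = np.polynomial.polynomial.polyfit(gws, vals, 2)
        rng = gw_range if gw_range is not None else (float(gws[0]), float(gws[-1]))
        return cls(transporter, tuple(float(c) for c in coeffs), rng, term_gw)


# Anchors from inverting K = CL_PD/(CL_PD + R*CL_eff) at the published
# GW15/GW25 steady-state unbound ratios with the term clearances:
#   P-gp  (nelfinavir, 240/350, term GW38): K(25)=0.34, K(15)=0.23
#   BCRP  (efavirenz, 1480/2200, term GW39): K(25)=0.33, K(15)=0.27
_DEFAULT_ANCHORS: dict[str, tuple[dict[float, float], float]] = {
    "P-gp": ({15.0: 240 * (1 - 0.23) / (0.23 * 350),
              25.0: 240 * (1 - 0.34) / (0.34 * 350)}, 38.0),
    "BCRP": ({15.0: 1480 * (1 - 0.27) / (0.27 * 2200),
              25.0: 1480 * (1 - 0.33) / (0.33 * 2200)}, 39.0),
}


def default_abundance_curve(transporter: str) -> TransporterAbundanceCurve:
    """Default relative-abundance curve for ``"P-gp"`` or ``"BCRP"``."""
    try:
        anchors, term = _DEFAULT_ANCHORS[transporter]
    except KeyError:
        raise KeyError(
            f"unknown transporter {transporter!r}; known: {sorted(_DEFAULT_ANCHORS)}"
        ) from None
    return TransporterAbundanceCurve.from_anchors(transporter, anchors, term)


def relative_abundance(
    curve: TransporterAbundanceCurve, gw: "GestationalWeek | float"
) -> float:
    """Transporter abundance at ``gw`` relative to term (term = 1.0)."""
    return curve(gw)
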