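"""Electrochemical product-analysis metrics for glycerol oxidation.

Once HPLC quantification has produced product concentrations, these metrics
interpret them against the charge passed during (photo)electrolysis:

* relative selectivity  RS_i = n_i / Σ n_j          (mole fraction, %)
* Faradaic efficiency   FE_i = q_i · n_i · F / Q_total   (%)
* GOR charge            Q_GOR = F · Σ q_i · n_i
* total FE              FE_total = Q_GOR / Q_total = Σ FE_i

where q_i is the number of electrons consumed to oxidize one glycerol
molecule to product i.  Defaults ship for the common glycerol oxidation
products: DHA and GLAD need 2 electrons each, GCAD 4/3, FA 8/3 (fractional
because one glycerol yields several molecules of the smaller products).
Glycerol itself is the reactant and never carries a q.

FE_total is a built-in sanity check: values above 100% are impossible and
flag a quantification error (classically, attributing a co-eluting
glycerol+DHA peak entirely to DHA), so such values are reported with a
warning, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "FARADAY",
    "ProductSpec",
    "DEFAULT_PRODUCT_SPECS",
    "ElectrolysisRecord",
    "total_charge",
    "concentration_from_charge",
    "relative_selectivity",
    "faradaic_efficiency",
    "gor_charge_and_fe_total",
    "to_rhe",
    "format_pec_report",
]

#: Faraday constant, C/mol.  Fixed (not configurable) so worked examples
#: stay exact.
FARADAY = 96485.0

#: Default Nernst coefficient for the pH term of the RHE conversion, V/pH.
NERNST_SLOPE_V_PER_PH = 0.059

#: Standard potential of the Ag/AgCl (sat. KCl) reference electrode, V.
AG_AGCL_OFFSET_V = 0.197


@dataclass(frozen=True)
class ProductSpec:
    """A glycerol-oxidation product and its electron count q (electrons per
    product molecule, possibly fractional)."""

    name: str
    q: Fraction

    def __post_init__(self) -> None:
        q = Fraction(self.q)
        object.__setattr__(self, "q", q)
        if q <= 0:
            raise ValueError("electron count q must be positive")


#: Electron counts for the common glycerol oxidation products.
DEFAULT_PRODUCT_SPECS: dict[str, ProductSpec] = {
    "DHA": ProductSpec("DHA", Fraction(2)),
    "GLAD": ProductSpec("GLAD", Fraction(2)),
    "GCAD": ProductSpec("GCAD", Fraction(4, 3)),
    "FA": ProductSpec("FA", Fraction(8, 3)),
}


@dataclass(frozen=True)
class ElectrolysisRecord:
    """Context of one electrolysis run: total charge passed (C), electrolyte
    volume (L), and optional electrode area / potential / pH / duration
    metadata."""

    q_total: float
    volume_l: float
    electrode_area_cm2: float | None = None
    applied_potential_v_rhe: float | None = None
    ph: float | None = None
    duration_h: float | None = None

    def __post_init__(self) -> None:
        if self.q_total < 0:
            raise ValueError("total charge must be >= 0")
        if self.volume_l <= 0:
            raise ValueError("electrolyte volume must be positive")


def total_charge(current_a: float, duration_s: float) -> float:
    """Charge in coulombs for a constant current: ``Q = I·t``.

    5 mA held for 10 h (36000 s) gives 180 C — the scale of a typical
    lab electrolysis.
    """
    if current_a < 0 or duration_s < 0:
        raise DomainError("current and duration must be non-negative")
    return current_a * duration_s


def concentration_from_charge(
    q_total: float, selectivity: float, q: float | Fraction, volume_l: float
) -> float:
    """Product concentration (mM) implied by charge bookkeeping:
    ``c = Q·s / (q·F·V)``.

    ``selectivity`` is the fraction of the charge that went to this product
    (0..1), ``q`` its electrons per molecule, ``volume_l`` the electrolyte
    volume.  180 C at 50% selectivity toward a 2-electron product in 0.1 L
    gives 4.66 mM.
    """
    if not (0.0 <= selectivity <= 1.0):
        raise DomainError("selectivity must be a fraction in [0, 1]")
    if volume_l <= 0:
        raise DomainError("volume must be positive")
    qf = float(q)
    if qf <= 0:
        raise DomainError("electron count q must be positive")
    moles = q_total * selectivity / (qf * FARADAY)
    return 1000.0 * moles / volume_l  # mol/L -> mM


def relative_selectivity(amounts: Mapping[str, float]) -> dict[str, float]:
    """Per-product relative selectivity RS_i = 100·n_i/Σn_j (%).

    ``amounts`` maps product name to moles (or to concentration — RS is a
    ratio, so any common volume cancels).  Percentages sum to 100 before
    rounding.  Negative amounts must be excluded upstream.
    """
    if any(v < 0 for v in amounts.values()):
        raise DomainError("product amounts must be non-negative")
    total = float(sum(amounts.values()))
    if total <= 0:
        raise DomainError("total product amount must be positive")
    return {name: 100.0 * v / total for name, v in amounts.items()}


def faradaic_efficiency(n_mol: float, q: float | Fraction, q_total: float) -> float:
    """Faradaic efficiency (%) of one product: ``FE = 100·q·n·F / Q_total``.

    May exceed 100%, which signals a quantification error upstream; the
    value is reported as-is.
    """
    if q_total <= 0:
        raise DomainError("total charge must be positive")
    if n_mol < 0:
        raise DomainError("product amount must be non-negative")
    return 100.0 * float(q) * n_mol * FARADAY / q_total


def gor_charge_and_fe_total(
    amounts_mol: Mapping[str, float],
    record: ElectrolysisRecord,
    specs: Mapping[str, ProductSpec] | None = None,
) -> tuple[float, float]:
    """Charge consumed by glycerol oxidation and total Faradaic efficiency.

    ``Q_GOR = F·Σ q_i·n_i`` and ``FE_total = 100·Q_GOR/Q_total``, which by
    construction equals Σ FE_i.  Every product in ``amounts_mol`` needs a
    spec (electron count); an empty product set gives (0, 0).
    """
    if specs is None:
        specs = DEFAULT_PRODUCT_SPECS
    q_gor = 0.0
    for name, n in amounts_mol.items():
        if name not in specs:
            raise ConfigurationError(
                f"no electron count (q) known for product {name!r}"
            )
        if n < 0:
            raise DomainError(f"negative amount for product {name!r}")
        q_gor += float(specs[name].q) * n
    q_gor *= FARADAY
    if record.q_total <= 0:
        if q_gor == 0.0:
            return 0.0, 0.0
        raise DomainError("total charge must be positive when products exist")
    return q_gor, 100.0 * q_gor / record.q_total


def to_rhe(
    v_ref: float,
    ph: float,
    reference_offset_v: float = AG_AGCL_OFFSET_V,
    nernst_slope: float = NERNST_SLOPE_V_PER_PH,
) -> float:
    """Convert a potential vs. Ag/AgCl (sat. KCl) to the RHE scale:
    ``V_RHE = V_ref + 0.197 + 0.059·pH`` by default."""
    return v_ref + reference_offset_v + nernst_slope * ph


def format_pec_report(
    concentrations_mm: Mapping[str, float],
    record: ElectrolysisRecord,
    specs: Mapping[str, ProductSpec] | None = None,
) -> str:
    """Plain-text product-analysis report: per-product concentration, RS and
    FE, plus Q_GOR and FE_total, with a prominent warning when FE_total
    exceeds 100%."""
    if specs is None:
        specs = DEFAULT_PRODUCT_SPECS
    amounts = {
        name: c * 1e-3 * record.volume_l for name, c in concentrations_mm.items()
    }
    rs = relative_selectivity(concentrations_mm)
    lines = ["product analysis report", "-----------------------"]
    fe_by_product = {}
    for name, c in concentrations_mm.items():
        if name not in specs:
            raise ConfigurationError(
                f"no electron count (q) known for product {name!r}"
            )
        fe = faradaic_efficiency(amounts[name], specs[name].q, record.q_total)
        fe_by_product[name] = fe
        lines.append(
            f"{name}: {c:.3g} mM | RS {rs[name]:.1f}% | FE {fe:.1f}%"
        )
    q_gor, fe_total = gor_charge_and_fe_total(amounts, record, specs)
    lines.append(f"Q_GOR: {q_gor:.3g} C of {record.q_total:.3g} C passed")
    lines.append(f"FE_total: {fe_total:.1f}%")
    if fe_total > 100.0:
        lines.append(
            "*** WARNING: FE_total exceeds 100% — this is physically "
            "impossible and indicates a quantification error (e.g. a "
            "co-eluting peak attributed to a single product) ***"
        )
    return "\n".join(lines)
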