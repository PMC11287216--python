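"""Carbonate speciation and radiotracer rate normalization.

Dark DIC-assimilation assays measure uptake of a ¹⁴C-bicarbonate spike in
disintegrations per minute (DPM) per gram dry-weight sediment (gdws) per
hour. Converting that signal to a total DIC assimilation rate requires
(1) estimating the ambient DIC pool — dissolved CO2 is measured, bicarbonate
is inferred from pH via the Henderson–Hasselbalch equation with pKa 6.3 and
the two species are summed — and (2) scaling the label-specific rate by the
isotope-dilution factor (total DIC amount / labeled amount added).

Also provides the volumetric↔gravimetric unit conversion used to compare
sediment rates reported as µmol C cm⁻³ day⁻¹ with rates on a
nmol C gdws⁻¹ h⁻¹ basis, assuming a sediment density (default 2.0 g cm⁻³,
typical of sand-rich sediment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

#: definitional activity constant: disintegrations per minute per microcurie
DPM_PER_UCI = 2.22e6

#: first apparent dissociation constant of carbonic acid used throughout
DEFAULT_PKA = 6.3

#: specific activity of the ¹⁴C-bicarbonate label, µCi µmol⁻¹
DEFAULT_SPECIFIC_ACTIVITY = 52.0

#: amount of ¹⁴C-labeled DIC added per incubation, µmol
DEFAULT_LABEL_UMOL = 1.0

#: bulk density of sand-rich sediment, g cm⁻³ (typical range 1.7–2.3)
DEFAULT_SEDIMENT_DENSITY = 2.0


class GeochemDomainError(ValueError):
    """Raised for physically meaningless inputs (negative concentrations,
    nonpositive activities or densities)."""


@dataclass(frozen=True)
class PorewaterSample:
    """One depth horizon's porewater chemistry and tracer measurement."""

    depth_cm: float
    ph: float
    co2_uM: float
    dpm_rate: float  # DPM gdws^-1 h^-1
    specific_activity_uCi_per_umol: float = DEFAULT_SPECIFIC_ACTIVITY
    label_added_umol: float = DEFAULT_LABEL_UMOL

    def __post_init__(self) -> None:
        if not 0.0 <= self.ph <= 14.0:
            raise GeochemDomainError(f"pH {self.ph} outside [0, 14]")
        if self.co2_uM < 0:
            raise GeochemDomainError("co2_uM must be >= 0")
        if self.dpm_rate < 0:
            raise GeochemDomainError("dpm_rate must be >= 0")
        if self.specific_activity_uCi_per_umol <= 0:
            raise GeochemDomainError("specific activity must be > 0")
        if self.label_added_umol <= 0:
            raise GeochemDomainError("label amount must be > 0")


@dataclass(frozen=True)
class RateResult:
    """Speciation and normalized rate derived from one PorewaterSample."""

    depth_cm: float
    hco3_uM: float
    dic_uM: float
    dilution_factor: float
    rate_nmol_per_gdws_h: float


def bicarbonate_from_co2(co2_uM: float, ph: float, pka: float = DEFAULT_PKA) -> float:
    """[HCO3-] in µM from measured dissolved CO2 and pH.

    Henderson–Hasselbalch: pH = pKa + log10([HCO3-]/[CO2]), so
    [HCO3-] = [CO2] · 10^(pH − pKa). At pH = pKa the species are equal.
    """
    if co2_uM < 0:
        raise GeochemDomainError("co2_uM must be >= 0")
    return co2_uM * 10.0 ** (ph - pka)


def bicarbonate_fraction(ph: float, pka: float = DEFAULT_PKA) -> float:
    """Fraction of the CO2+HCO3- pool present as bicarbonate; 0.5 at pH=pKa."""
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def total_dic(co2_uM: float, hco3_uM: float) -> float:
    """Total dissolved inorganic carbon: the sum of the two species, µM."""
    if co2_uM < 0 or hco3_uM < 0:
        raise GeochemDomainError("concentrations must be >= 0")
    return co2_uM + hco3_uM


def dilution_factor(
    dic_uM: float, porewater_volume_mL: float, label_added_umol: float = DEFAULT_LABEL_UMOL
) -> float:
    """Isotope-dilution factor = total DIC amount / labeled amount.

    The total pool is the ambient DIC in the incubated porewater volume plus
    the added label itself (the spike joins the pool it labels). µM × mL
    gives nmol; /1000 gives µmol.
    """
    if porewater_volume_mL <= 0 or label_added_umol <= 0:
        raise GeochemDomainError("volume and label amount must be > 0")
    if dic_uM < 0:
        raise GeochemDomainError("dic_uM must be >= 0")
    ambient_umol = dic_uM * porewater_volume_mL / 1000.0
    return (ambient_umol + label_added_umol) / label_added_umol


def radiotracer_rate(
    dpm_rate: float,
    specific_activity_uCi_per_umol: float = DEFAULT_SPECIFIC_ACTIVITY,
    dilution_factor: float = 1.0,
    dpm_per_uci: float = DPM_PER_UCI,
) -> float:
    """Total DIC assimilation rate, nmol C gdws⁻¹ h⁻¹.

    DPM → µCi → µmol label via the specific activity, scaled by the isotope
    dilution factor and converted µmol → nmol. Linear separately in
    ``dpm_rate`` and ``dilution_factor``.
    """
    if dpm_rate < 0:
        raise GeochemDomainError("dpm_rate must be >= 0")
    if specific_activity_uCi_per_umol <= 0 or dilution_factor <= 0 or dpm_per_uci <= 0:
        raise GeochemDomainError("specific activity, dilution factor and DPM/µCi must be > 0")
    umol_rate = dpm_rate / (dpm_per_uci * specific_activity_uCi_per_umol)
    return umol_rate * dilution_factor * 1000.0


def volumetric_to_gravimetric(
    rate_umol_per_cm3_day: float, density_g_per_cm3: float = DEFAULT_SEDIMENT_DENSITY
) -> float:
    """µmol C cm⁻³ day⁻¹ → nmol C gdws⁻¹ h⁻¹ at the given sediment density."""
    if density_g_per_cm3 <= 0:
        raise GeochemDomainError("density must be > 0")
    return rate_umol_per_cm3_day * 1000.0 / (density_g_per_cm3 * 24.0)


def gravimetric_to_volumetric(
    rate_nmol_per_gdws_h: float, density_g_per_cm3: float = DEFAULT_SEDIMENT_DENSITY
) -> float:
    """Inverse of :func:`volumetric_to_gravimetric`."""
    if density_g_per_cm3 <= 0:
        raise GeochemDomainError("density must be > 0")
    return rate_nmol_per_gdws_h * density_g_per_cm3 * 24.0 / 1000.0


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def normalize_sample(
    sample: PorewaterSample,
    pka: float = DEFAULT_PKA,
    porewater_volume_mL: float = 10.0,
) -> RateResult:
    """Full speciation + normalization for one sample."""
    hco3 = bicarbonate_from_co2(sample.co2_uM, sample.ph, pka)
    dic = total_dic(sample.co2_uM, hco3)
    dil = dilution_factor(dic, porewater_volume_mL, sample.label_added_umol)
    rate = radiotracer_rate(sample.dpm_rate, sample.specific_activity_uCi_per_umol, dil)
    return RateResult(
        depth_cm=sample.depth_cm,
        hco3_uM=hco3,
        dic_uM=dic,
        dilution_factor=dil,
        rate_nmol_per_gdws_h=rate,
    )


def process_porewater(
    table: pd.DataFrame,
    pka: float = DEFAULT_PKA,
    specific_activity: float = DEFAULT_SPECIFIC_ACTIVITY,
    label_added_umol: float = DEFAULT_LABEL_UMOL,
    porewater_volume_mL: float = 10.0,
) -> pd.DataFrame:
    """Normalize a porewater table (columns depth_cm, ph, co2_uM, dpm_rate;
    optional specific_activity_uCi_per_umol, label_added_umol) to total DIC
    assimilation rates. Returns one row per input row."""
    required = {"depth_cm", "ph", "co2_uM", "dpm_rate"}
    missing = required - set(table.columns)
    if missing:
        raise GeochemDomainError(f"porewater table missing column(s): {sorted(missing)}")
    rows = []
    for rec in table.to_dict("records"):
        sample = PorewaterSample(
            depth_cm=float(rec["depth_cm"]),
            ph=float(rec["ph"]),
            co2_uM=float(rec["co2_uM"]),
            dpm_rate=float(rec["dpm_rate"]),
            specific_activity_uCi_per_umol=float(
                rec.get("specific_activity_uCi_per_umol", specific_activity)
            ),
            label_added_umol=float(rec.get("label_added_umol", label_added_umol)),
        )
        res = normalize_sample(sample, pka=pka, porewater_volume_mL=porewater_volume_mL)
        rows.append(
            {
                "depth_cm": res.depth_cm,
                "ph": sample.ph,
                "co2_uM": sample.co2_uM,
                "hco3_uM": res.hco3_uM,
                "dic_uM": res.dic_uM,
                "dilution_factor": res.dilution_factor,
                "rate_nmol_per_gdws_h": res.rate_nmol_per_gdws_h,
            }
        )
    return pd.DataFrame(rows)
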