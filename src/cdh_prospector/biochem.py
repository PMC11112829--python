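"""Biochemical calculators for enzyme characterisation.

Covers the routine arithmetic of a purification and characterisation
campaign: volumetric/specific activities from absorbance slopes (one unit
oxidizes 1 µmol of electron acceptor per minute), limit of quantification
from blank replicates, multi-step purification tables (total protein,
yields, purification factors, RZ purity ratios), molar absorption
coefficients from sequence, protein concentration from A280, FAD occupancy
from TCA-released flavin with iterative protein correction, normalization
of specific activity to 100 % FAD loading, and UV-Vis feature extraction
(Soret band position/shift, α/β bands, difference spectra).

Absorbances are in AU, extinction coefficients in mM⁻¹ cm⁻¹ unless noted,
path lengths in cm, times in minutes, activities in U (µmol min⁻¹).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

BDL = None  # below-detection-limit marker in activity inputs


# ---------------------------------------------------------------------------
# assays

@dataclass(frozen=True)
class AssayConfig:
    """Electron-acceptor assay parameters."""

    acceptor: str
    wavelength_nm: float
    extinction_mM: float
    path_cm: float = 1.0
    substrate: str = ""
    buffer: str = ""

    def __post_init__(self) -> None:
        if self.extinction_mM <= 0 or self.wavelength_nm <= 0:
            raise ValueError("wavelength and extinction must be positive")


#: standard presets: DCIP at 520 nm (pH 4–6) and 600 nm (pH 8),
#: cytochrome c at 550 nm
DCIP_520 = AssayConfig("DCIP", 520, 6.9)
DCIP_600 = AssayConfig("DCIP", 600, 11.8)
CYTC_550 = AssayConfig("cytochrome c", 550, 19.6)


@dataclass
class AssayMeasurement:
    """An absorbance-vs-time trace or a precomputed slope.

    ``sample_fraction`` is the enzyme-sample share of the reaction volume;
    ``dilution`` the pre-dilution of the sample.
    """

    time_min: np.ndarray | None = None
    absorbance: np.ndarray | None = None
    slope_au_per_min: float | None = None
    dilution: float = 1.0
    sample_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.dilution < 1:
            raise ValueError("dilution must be >= 1")
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.time_min is not None:
            t = np.asarray(self.time_min, dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValueError("time points must be strictly increasing")


def volumetric_activity(
    m: AssayMeasurement,
    cfg: AssayConfig,
    r2_floor: float = 0.95,
) -> float:
    """Activity in U per mL of enzyme sample from an absorbance slope.

    The slope (AU min⁻¹, least-squares over the trace) divided by ε·path
    gives the acceptor turnover in mM min⁻¹ = µmol min⁻¹ mL⁻¹ of reaction;
    scaling by reaction/sample volume and dilution refers it to the
    undiluted sample.  Negative fitted slopes clip to zero with a warning.
    """
    if m.slope_au_per_min is not None:
        slope = m.slope_au_per_min
    else:
        if m.time_min is None or m.absorbance is None or len(m.time_min) < 3:
            raise ValueError("need a slope or a trace with >= 3 points")
        fit = stats.linregress(np.asarray(m.time_min, float),
                               np.asarray(m.absorbance, float))
        slope = float(fit.slope)
        if fit.rvalue ** 2 < r2_floor:
            warnings.warn(f"trace nonlinearity: R^2 = {fit.rvalue**2:.3f} "
                          f"below {r2_floor}")
    if slope < 0:
        warnings.warn("negative fitted slope clipped to 0")
        return 0.0
    return (slope / (cfg.extinction_mM * cfg.path_cm)
            * m.dilution / m.sample_fraction)


def limit_of_quantification(blank_activities: Sequence[float]) -> float:
    """10 × sample standard deviation (n−1) of blank-reaction activities."""
    if len(blank_activities) < 3:
        raise ValueError("need >= 3 blank replicates")
    return 10.0 * float(np.std(np.asarray(blank_activities, float), ddof=1))


# ---------------------------------------------------------------------------
# purification tables

@dataclass
class PurificationStep:
    """One row of a purification table.

    ``activities`` maps assay labels (e.g. ``"dcip"``, ``"cytc"``) to total
    activities in U; ``None`` marks below-detection-limit, which is a
    distinct state and never coerced to zero.
    """

    label: str
    volume_ml: float
    protein_conc_mg_ml: float
    activities: dict[str, float | None] = field(default_factory=dict)
    conc_method: Literal["bradford", "a280"] = "bradford"
    a420: float | None = None
    a280: float | None = None
    #: pre-computed A420/A280 purity ratio, when the raw absorbances are
    #: not available (e.g. transcribing an instrument report)
    rz_measured: float | None = None

    def __post_init__(self) -> None:
        if self.volume_ml < 0 or self.protein_conc_mg_ml < 0:
            raise ValueError("volumes and concentrations must be >= 0")

    @property
    def total_protein_mg(self) -> float:
        return self.volume_ml * self.protein_conc_mg_ml

    @property
    def rz(self) -> float | None:
        if self.rz_measured is not None:
            return self.rz_measured
        if self.a420 is None or self.a280 in (None, 0):
            return None
        return self.a420 / self.a280


def purification_table(
    steps: Sequence[PurificationStep],
    reference: int | str = 0,
) -> pd.DataFrame:
    """Derived columns for a multi-step purification.

    Per step and assay: total protein = concentration × volume, specific
    activity = total activity / total protein, yield (%) and purification
    factor relative to the reference step (the starting supernatant).
    b.d.l. activities propagate as NaN (rendered "b.d.l."); computations
    keep full precision — round only for display.
    """
    if isinstance(reference, str):
        ref_idx = next(i for i, s in enumerate(steps) if s.label == reference)
    else:
        ref_idx = reference
    ref = steps[ref_idx]
    assays: list[str] = []
    for s in steps:
        for a in s.activities:
            if a not in assays:
                assays.append(a)
    rows = []
    for s in steps:
        row: dict[str, object] = {
            "step": s.label,
            "volume_ml": s.volume_ml,
            "protein_conc_mg_ml": s.protein_conc_mg_ml,
            "conc_method": s.conc_method,
            "total_protein_mg": s.total_protein_mg,
            "rz": s.rz if s.rz is not None else np.nan,
        }
        for a in assays:
            act = s.activities.get(a, BDL)
            ref_act = ref.activities.get(a, BDL)
            if ref_act in (BDL, 0):
                raise ValueError(
                    f"reference step has no usable {a} activity")
            bdl = act is BDL
            total = np.nan if bdl else float(act)
            spec = np.nan if bdl else total / s.total_protein_mg
            ref_spec = ref_act / ref.total_protein_mg
            row[f"total_activity_U[{a}]"] = total
            row[f"specific_activity_U_mg[{a}]"] = spec
            row[f"yield_pct[{a}]"] = np.nan if bdl else 100.0 * total / ref_act
            row[f"purification_factor[{a}]"] = (np.nan if bdl
                                                else spec / ref_spec)
            row[f"bdl[{a}]"] = bdl
        rows.append(row)
    df = pd.DataFrame(rows).set_index("step")
    if len({s.conc_method for s in steps}) > 1:
        df.attrs["mixed_concentration_methods"] = True
    return df


def format_table(df: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Display form: rounded numbers, b.d.l. rendered explicitly."""
    out = df.copy()
    for col in out.columns:
        if col.startswith("bdl["):
            continue
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(decimals)
    for col in [c for c in out.columns if c.startswith("bdl[")]:
        assay = col[4:-1]
        for target in (f"total_activity_U[{assay}]",
                       f"specific_activity_U_mg[{assay}]",
                       f"yield_pct[{assay}]",
                       f"purification_factor[{assay}]"):
            out[target] = out[target].astype(object)
            out.loc[out[col], target] = "b.d.l."
        del out[col]
    return out


# ---------------------------------------------------------------------------
# concentrations and cofactor loading

#: chromophore molar absorptivities at 280 nm (M⁻¹ cm⁻¹)
EPS_TRP, EPS_TYR, EPS_CYSTINE = 5500.0, 1490.0, 125.0


def epsilon280_from_sequence(
    sequence: str,
    cysteines: Literal["paired", "reduced"] = "paired",
) -> float:
    """ε₂₈₀ (M⁻¹ cm⁻¹) from Trp/Tyr/cystine counts of the mature sequence.

    The default assumes all cysteines pair into cystines (⌊nCys/2⌋),
    matching the convention of common web calculators for secreted
    proteins; ``reduced`` counts none.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    n_trp, n_tyr, n_cys = seq.count("W"), seq.count("Y"), seq.count("C")
    cystines = n_cys // 2 if cysteines == "paired" else 0
    return EPS_TRP * n_trp + EPS_TYR * n_tyr + EPS_CYSTINE * cystines


@dataclass(frozen=True)
class ProteinConc:
    molar_M: float
    mass_g_per_L: float


def protein_conc(a280: float, epsilon280_M: float, molar_mass: float,
                 path_cm: float = 1.0) -> ProteinConc:
    """Molar and mass concentration from A280 (Beer–Lambert)."""
    if a280 < 0 or epsilon280_M <= 0 or molar_mass <= 0 or path_cm <= 0:
        raise ValueError("inputs must be positive (A280 >= 0)")
    molar = a280 / (epsilon280_M * path_cm)
    return ProteinConc(molar, molar * molar_mass)


def fad_occupancy(
    a450_after_tca: float,
    a280_native: float,
    eps_fad450_mM: float = 11.3,
    eps_prot280_mM: float = 100.185,
    eps_fad280_mM: float = 0.0,
    path_cm: float = 1.0,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> float:
    """Fraction of enzyme molecules carrying FAD.

    The flavin released by TCA precipitation is quantified at 450 nm; the
    protein is quantified at 280 nm of the native sample, iteratively
    corrected for the flavin's own 280 nm absorbance (fixed-point
    P ← (A280 − [FAD]·ε_FAD,280)/ε_prot,280 until converged).  With the
    default ε_FAD,280 = 0 the uncorrected single-step estimate is
    returned.  Results are clipped to [0, 1.05]; values above 1 warn.
    """
    if a450_after_tca < 0 or a280_native <= 0:
        raise ValueError("absorbances must be positive (A450 >= 0)")
    fad_mM = a450_after_tca / (eps_fad450_mM * path_cm)
    prot_mM = a280_native / (eps_prot280_mM * path_cm)
    for _ in range(max_iter):
        corrected = a280_native - fad_mM * eps_fad280_mM * path_cm
        if corrected <= 0:
            raise ValueError("flavin correction exceeds native A280")
        nxt = corrected / (eps_prot280_mM * path_cm)
        if abs(nxt - prot_mM) < tol:
            prot_mM = nxt
            break
        prot_mM = nxt
    else:
        raise ValueError("FAD occupancy iteration did not converge")
    occ = fad_mM / prot_mM
    if occ > 1.0:
        warnings.warn(f"FAD occupancy {occ:.3f} > 1; clipped at 1.05")
    return float(min(max(occ, 0.0), 1.05))


def normalize_to_full_fad(
    specific_activity: float,
    occupancy: float,
    activity_sd: float | None = None,
    occupancy_sd: float | None = None,
) -> float | tuple[float, float]:
    """Specific activity rescaled to 100 % FAD loading.

    Only flavin-loaded molecules turn over, so the catalytically fair
    comparison between preparations divides by the occupancy.  When
    standard deviations are supplied, relative errors add in quadrature.
    """
    if not 0 < occupancy <= 1:
        raise ValueError("occupancy must be in (0, 1]")
    value = specific_activity / occupancy
    if activity_sd is None and occupancy_sd is None:
        return value
    rel = 0.0
    if activity_sd is not None and specific_activity != 0:
        rel += (activity_sd / specific_activity) ** 2
    if occupancy_sd is not None:
        rel += (occupancy_sd / occupancy) ** 2
    return value, value * math.sqrt(rel)


# ---------------------------------------------------------------------------
# spectra

@dataclass
class Spectrum:
    """A UV-Vis absorbance spectrum on a strictly increasing nm grid."""

    wavelength_nm: np.ndarray
    absorbance: np.ndarray
    state: Literal["oxidized", "reduced"] = "oxidized"

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, float)
        self.absorbance = np.asarray(self.absorbance, float)
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.wavelength_nm.shape != self.absorbance.shape:
            raise ValueError("grid and absorbance shapes differ")

    def at(self, nm: float) -> float:
        return float(np.interp(nm, self.wavelength_nm, self.absorbance))

    @classmethod
    def from_tsv(cls, path, state="oxidized") -> "Spectrum":
        data = np.loadtxt(path)
        return cls(data[:, 0], data[:, 1], state)


def _peak_in_window(s: Spectrum, lo: float, hi: float) -> float | None:
    """Quadratically refined local maximum inside [lo, hi]; None if the
    window holds no interior local maximum."""
    mask = (s.wavelength_nm >= lo) & (s.wavelength_nm <= hi)
    idx = np.flatnonzero(mask)
    if len(idx) < 3:
        return None
    sub_w, sub_a = s.wavelength_nm[idx], s.absorbance[idx]
    k = int(np.argmax(sub_a))
    if k == 0 or k == len(idx) - 1:
        return None
    if not (sub_a[k] > sub_a[k - 1] or sub_a[k] > sub_a[k + 1]):
        return None  # flat: no genuine band
    y0, y1, y2 = sub_a[k - 1], sub_a[k], sub_a[k + 1]
    denom = y0 - 2 * y1 + y2
    offset = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    step = (sub_w[k + 1] - sub_w[k - 1]) / 2
    return float(sub_w[k] + offset * step)


@dataclass
class SpectralFeatures:
    soret_ox_nm: float | None
    soret_red_nm: float | None
    soret_shift_nm: float | None
    rz: float
    alpha_band_nm: float | None
    alpha_amplitude: float | None
    beta_band_nm: float | None
    beta_amplitude: float | None
    difference_nm: np.ndarray
    difference_au: np.ndarray

    @property
    def has_soret(self) -> bool:
        return self.soret_ox_nm is not None


def spectral_features(
    ox: Spectrum,
    red: Spectrum,
    soret_window: tuple[float, float] = (400.0, 440.0),
    alpha_window: tuple[float, float] = (548.0, 570.0),
    beta_window: tuple[float, float] = (520.0, 545.0),
) -> SpectralFeatures:
    """Heme/flavin features of an oxidized/reduced spectrum pair.

    Reports Soret maxima (flavocytochromes: ~420 nm oxidized, red-shifting
    to ~429 nm on substrate reduction), the shift, RZ = A420/A280 of the
    oxidized spectrum, reduced-state α/β band positions and amplitudes,
    and the difference spectrum (reduced − oxidized) on the overlapping
    grid.  A missing Soret maximum (flat window) flags a heme-free sample
    such as an isolated DH domain.
    """
    for s in (ox, red):
        if s.wavelength_nm[0] > 260 or s.wavelength_nm[-1] < 600:
            raise ValueError("spectra must cover at least 260-600 nm")
    soret_ox = _peak_in_window(ox, *soret_window)
    soret_red = _peak_in_window(red, *soret_window)
    shift = (soret_red - soret_ox
             if soret_ox is not None and soret_red is not None else None)
    alpha = _peak_in_window(red, *alpha_window)
    beta = _peak_in_window(red, *beta_window)
    lo = max(ox.wavelength_nm[0], red.wavelength_nm[0])
    hi = min(ox.wavelength_nm[-1], red.wavelength_nm[-1])
    grid = ox.wavelength_nm[(ox.wavelength_nm >= lo)
                            & (ox.wavelength_nm <= hi)]
    diff = np.array([red.at(w) - ox.at(w) for w in grid])
    return SpectralFeatures(
        soret_ox_nm=soret_ox,
        soret_red_nm=soret_red,
        soret_shift_nm=shift,
        rz=ox.at(420.0) / ox.at(280.0),
        alpha_band_nm=alpha,
        alpha_amplitude=red.at(alpha) if alpha is not None else None,
        beta_band_nm=beta,
        beta_amplitude=red.at(beta) if beta is not None else None,
        difference_nm=grid,
        difference_au=diff,
    )
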