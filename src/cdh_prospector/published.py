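"""Published characterisation data for a recombinant class III CDH.

Measured *inputs* from the published purification and characterisation of
the Fusarium solani CDH (FsCDH) produced in Komagataella phaffii: step
volumes, total protein, total activities per assay and purity ratios for
the full-length enzyme and its proteolytically released DH domain, plus
the specific activities and FAD occupancies of characterised comparison
enzymes.  Every *derived* column (specific activity, yield, purification
factor, 100 %-FAD-normalised activity) is recomputed by the calculators in
:mod:`~cdh_prospector.biochem` — nothing derived is stored here.
"""

from __future__ import annotations

from .biochem import PurificationStep

#: molar absorption coefficients of the mature proteins (mM⁻¹ cm⁻¹)
EPS280_FSCDH_mM = 100.185
EPS280_FSDH_mM = 77.6

#: A280-based protein concentrations of the final AEX pools (mg mL⁻¹)
AEX_CONC_A280_FSCDH = 9.9
AEX_CONC_A280_FSDH = 11.8


def fscdh_purification_steps() -> list[PurificationStep]:
    """Full-length FsCDH purification: supernatant -> HIC -> AEX.

    Protein by Bradford; activities are totals in U for the DCIP and
    cytochrome c assays.
    """
    return [
        PurificationStep("Supernat.", 4500, 1310 / 4500,
                         {"dcip": 946.0, "cytc": 47.0}),
        PurificationStep("HIC (CDH)", 750, 598 / 750,
                         {"dcip": 542.0, "cytc": 14.0}, rz_measured=0.33),
        PurificationStep("AEX (CDH)", 15, 68 / 15,
                         {"dcip": 111.0, "cytc": 8.0}, rz_measured=0.53),
    ]


def fsdh_purification_steps() -> list[PurificationStep]:
    """Isolated DH-domain pool; cytochrome c activity is below detection
    after HIC, as expected without the cytochrome domain."""
    return [
        PurificationStep("Supernat.", 4500, 1310 / 4500,
                         {"dcip": 946.0, "cytc": 47.0}),
        PurificationStep("HIC (DH)", 1800, 1120 / 1800,
                         {"dcip": 860.0, "cytc": None}, rz_measured=0.12),
        PurificationStep("AEX (DH)", 30, 183 / 30,
                         {"dcip": 399.0, "cytc": None}, rz_measured=0.02),
    ]


#: specific activity (U mg⁻¹, lactose/DCIP) and FAD occupancy of
#: characterised CDHs; activities are the measured (pre-rounding) values
#: the normalised column derives from
FAD_NORMALIZATION_INPUTS = {
    "FsCDH": {"specific_activity": 0.67, "activity_sd": 0.20,
              "occupancy": 0.09},
    "MtCDH": {"specific_activity": 1.59, "activity_sd": 0.32,
              "occupancy": 0.19},
    "CtCDH": {"specific_activity": 9.4, "activity_sd": 0.2,
              "occupancy": 0.44},
    "PcCDH": {"specific_activity": 23.4, "activity_sd": 1.0,
              "occupancy": 0.70},
}

#: measured FAD loadings of the recombinant preparations (fractions)
FAD_OCCUPANCY_FSCDH = 0.09
FAD_OCCUPANCY_FSDH = 0.13

#: Soret maxima of the oxidized and cellobiose-reduced full-length enzyme
SORET_OXIDIZED_NM = 420.0
SORET_REDUCED_NM = 429.0
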