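"""Physical constants for the microbioreactor model.

All values describe the culture medium (water at 37 °C), cancerous tissue and
PDMS at 37 °C. Concentrations are in mM throughout the package, lengths in the
mesh are in metres, and geometry configuration lengths in µm.
"""

# --- fluid (water, 37 °C) -------------------------------------------------
RHO_MEDIUM = 993.3        # kg/m^3
MU_MEDIUM = 0.000692      # Pa s

# --- diffusion coefficients, m^2/s ---------------------------------------
K_O2_MEDIUM = 2.6e-9      # O2 in water
K_O2_PDMS = 3.4e-9        # O2 in PDMS
K_O2_TISSUE = 1.83e-9     # O2 in cancerous tissue
K_GLC_MEDIUM = 9.27e-10   # glucose in water
K_GLC_TISSUE = 2.7e-10    # glucose in cancerous tissue

# --- partition (solubility) coefficients vs water, dimensionless ----------
S_O2_PDMS = 6.8
S_O2_TISSUE = 4.81
S_GLC_TISSUE = 1.0

# --- Michaelis-Menten uptake, default cell line ---------------------------
VMAX_O2 = 0.0203          # mM/s
KM_O2 = 0.00463           # mM
VMAX_GLC = 0.01076        # mM/s
KM_GLC = 0.04             # mM

# --- viability thresholds -------------------------------------------------
# Oxygen: quiescence below pO2 = 10 mmHg, necrosis near 0 mmHg.
O2_SOLUBILITY_ALPHA = 1.322e-3   # mM/mmHg, Henry solubility of O2 at 37 C
O2_QUIESCENT_MM = 0.01322        # = 10 mmHg * alpha
O2_NECROTIC_MM = 0.0
# Glucose: intervertebral-disc viability levels commonly used for tumor cells.
GLC_QUIESCENT_MM = 0.5
GLC_NECROTIC_MM = 0.2

# Maximum shear stress tolerated by cancer cells in culture, Pa.
SHEAR_THRESHOLD_PA = 25e-3

# Named Michaelis-Menten constant sets for glucose uptake in different cell
# types (screening presets for the reduced spherical model).
MM_PRESETS = {
    "mdt_ovarian_prostate": {"Vmax": 0.01076, "Km": 0.04},
    "breast_cancer_a": {"Vmax": 0.05773, "Km": 2.6},
    "breast_cancer_b": {"Vmax": 0.05206, "Km": 3.1},
    "breast_cancer_ra_treated": {"Vmax": 0.03596, "Km": 2.9},
}

UL_PER_MIN_TO_M3_PER_S = 1e-9 / 60.0
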