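"""Study defaults, kept in one versioned place rather than inline in logic.

These encode the screening protocol the package reproduces: the fixed
maximum particle dimension used for Shannon binning, the per-concentration
usable q-windows, the titration ratio ladder, the replicate count of the
noise-based uncertainty estimator, and the K_D search box.
"""

DEFAULTS_VERSION = 1

D_MAX_NM = 7.2

# usable q-window (nm^-1) by receptor-concentration tier (molar upper edge)
Q_WINDOW_TIERS = (
    (20e-6, (0.2, 2.0)),    # 20 uM and below
    (40e-6, (0.25, 2.5)),   # 40 uM
    (float("inf"), (0.3, 3.0)),  # above 80 uM (and 40-80 upper tier)
)

RATIO_LADDER = (0.0, 0.2, 0.6, 0.8, 0.9, 1.0, 1.1, 1.2, 1.5, 2.0, 4.0, 10.0)

N_NOISE_REPLICATES = 1000
KD_BOX_DECADES = 4.0
APO_OUTLIER_VR_THRESHOLD = 0.1   # V_R detectability floor
GUINIER_QRG_MAX = 1.3


def q_window_for_concentration(receptor_concentration: float) -> tuple[float, float]:
    """The protocol q-window for a given molar receptor concentration."""
    for upper, window in Q_WINDOW_TIERS:
        if receptor_concentration <= upper:
            return window
    return Q_WINDOW_TIERS[-1][1]
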