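"""The immutable registry of the 132 HRV features.

Every feature has a stable name, a family, and the analysis-window length
its family uses.  Downstream code (feature tables on disk, the classifier's
input layer, the CLI) relies on this ordering and must never reorder it.

Families and their sizes (sum = 132):

====================  =====  ==========
family                count  window (s)
====================  =====  ==========
basic                     4     270
variability              12     270
percentiles              28     270
dfa                       6     270/330
spectral                  4     270
spectral_adapted          4     270
resp_pole                 4     270
mse                      20     510
symbolic                  1     270
phase_coordination        2     270
phase_sync                7     270
higuchi                   1     270
teager                   21     270
arousal                   5     270
visibility               13     270
====================  =====  ==========
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

PERCENTILES = (5, 10, 25, 50, 75, 90, 95)
MSE_SCALES = tuple(range(1, 11))
SYNC_RATIOS = (6, 7, 8, 9)


@dataclass(frozen=True)
class FeatureDef:
    name: str
    family: str
    window_s: float
    units: str


def _build() -> tuple[FeatureDef, ...]:
    defs: list[FeatureDef] = []

    def add(name: str, family: str, window_s: float, units: str) -> None:
        defs.append(FeatureDef(name, family, window_s, units))

    # basic (4): means/medians of RR and HR on the absolute signal
    for name, units in (("mean_rr", "ms"), ("median_rr", "ms"),
                        ("mean_hr", "bpm"), ("median_hr", "bpm")):
        add(name, "basic", 270, units)

    # variability (12): six statistics on absolute and on detrended RR
    for stat in ("sdnn", "rr_range", "pnn50", "rmssd", "sdsd", "mad"):
        units = "%" if stat == "pnn50" else "ms"
        add(f"{stat}_abs", "variability", 270, units)
        add(f"{stat}_det", "variability", 270, units)

    # percentiles (28): 7 x {RR, HR} x {absolute, detrended}
    for signal, units in (("rr", "ms"), ("hr", "bpm")):
        for variant in ("abs", "det"):
            for p in PERCENTILES:
                add(f"{signal}_{variant}_p{p}", "percentiles", 270, units)

    # dfa (6)
    for name, win in (("dfa_alpha_all", 270), ("dfa_alpha_short", 270),
                      ("dfa_alpha_long", 270), ("dfa_f16", 270),
                      ("wdfa", 330), ("pdfa", 270)):
        add(name, "dfa", win, "ms" if name == "dfa_f16" else "1")

    # spectral (4)
    for name, units in (("vlf_ln", "ln(ms^2)"), ("lf_ln", "ln(ms^2)"),
                        ("hf_ln", "ln(ms^2)"), ("lf_hf_ratio", "1")):
        add(name, "spectral", 270, units)

    # spectral_adapted (4): HF band re-centred on the respiratory peak
    for name, units in (("vlf_ln_adapted", "ln(ms^2)"), ("lf_ln_adapted", "ln(ms^2)"),
                        ("hf_ln_adapted", "ln(ms^2)"), ("lf_hf_ratio_adapted", "1")):
        add(name, "spectral_adapted", 270, units)

    # resp_pole (4): respiratory frequency/power and the AR HF pole
    add("resp_freq", "resp_pole", 270, "Hz")
    add("resp_power_ln", "resp_pole", 270, "ln(ms^2)")
    add("hf_pole_phase", "resp_pole", 270, "rad")
    add("hf_pole_modulus", "resp_pole", 270, "1")

    # mse (20): sample entropy, m in {1, 2}, scales 1..10
    for m in (1, 2):
        for tau in MSE_SCALES:
            add(f"mse_m{m}_s{tau}", "mse", 510, "nats")

    # symbolic (1)
    add("symbolic_sampen", "symbolic", 270, "nats")

    # phase_coordination (2)
    add("phase_coord_short", "phase_coordination", 270, "fraction")
    add("phase_coord_long", "phase_coordination", 270, "fraction")

    # phase_sync (7)
    for n in SYNC_RATIOS:
        add(f"sync_rate_{n}2", "phase_sync", 270, "fraction")
    add("sync_dominant_ratio", "phase_sync", 270, "1")
    add("sync_short_term", "phase_sync", 270, "s")
    add("sync_long_term", "phase_sync", 270, "fraction")

    # higuchi (1)
    add("higuchi_fd", "higuchi", 270, "1")

    # teager (21): mean energy + 10 stats on each of {normalized IBI, IMF1}
    add("teager_mean_energy", "teager", 270, "1")
    for rep in ("ibi", "imf1"):
        for stat, units in (("pct_transitions", "%"), ("pct_maxima", "%"),
                            ("trans_ival_mean", "beats"), ("trans_ival_sd", "beats"),
                            ("max_ival_mean", "beats"), ("max_ival_sd", "beats"),
                            ("trans_amp_mean", "1"), ("trans_amp_sd", "1"),
                            ("max_amp_mean", "1"), ("max_amp_sd", "1")):
            add(f"teager_{rep}_{stat}", "teager", 270, units)

    # arousal (5)
    for stat in ("max", "mean", "median", "min", "sd"):
        add(f"arousal_{stat}", "arousal", 270, "probability")

    # visibility (13): 8 from the natural visibility graph, 5 from the
    # difference visibility graph
    for name in ("nvg_assortativity", "nvg_clust_mean", "nvg_clust_sd",
                 "nvg_degree_mean", "nvg_degree_sd", "nvg_powerlaw_slope",
                 "nvg_pct_low_degree", "nvg_pct_high_degree",
                 "dvg_degree_mean", "dvg_degree_sd", "dvg_powerlaw_slope",
                 "dvg_pct_low_degree", "dvg_pct_high_degree"):
        add(name, "visibility", 270, "1" if "pct" not in name else "%")

    return tuple(defs)


REGISTRY: tuple[FeatureDef, ...] = _build()
N_FEATURES = len(REGISTRY)

FAMILY_COUNTS = {
    "basic": 4, "variability": 12, "percentiles": 28, "dfa": 6,
    "spectral": 4, "spectral_adapted": 4, "resp_pole": 4, "mse": 20,
    "symbolic": 1, "phase_coordination": 2, "phase_sync": 7, "higuchi": 1,
    "teager": 21, "arousal": 5, "visibility": 13,
}


@lru_cache(maxsize=None)
def feature_names() -> tuple[str, ...]:
    return tuple(d.name for d in REGISTRY)


@lru_cache(maxsize=None)
def feature_index(name: str) -> int:
    return feature_names().index(name)


def family_slice(family: str) -> slice:
    """Contiguous column slice of a family in registry order."""
    idx = [i for i, d in enumerate(REGISTRY) if d.family == family]
    if not idx:
        raise KeyError(family)
    if idx != list(range(idx[0], idx[-1] + 1)):
        raise AssertionError("registry families must be contiguous")
    return slice(idx[0], idx[-1] + 1)


def registry_table() -> "list[dict]":
    """Machine-readable listing (name, family, window, units) for auditing."""
    return [{"index": i, "name": d.name, "family": d.family,
             "window_s": d.window_s, "units": d.units}
            for i, d in enumerate(REGISTRY)]
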