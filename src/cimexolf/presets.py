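"""Default generative archetypes for the six sensillum types.

The preset encodes, as editable configuration, the qualitative response
structure of the bed-bug antenna at the 1:100 v/v reference dose:

* aldehyde-dominated smooth-peg **D** types, with nonanal the strongest
  stimulus anywhere on the antenna (248.5 spikes/s on Dα) and broad
  aldehyde/ketone/halide sensitivity on Dβ;
* the amine-specialist grooved-peg **C** type (ammonia, propylamine,
  butylamine, plus the heterocyclics 1-methylpiperazine and thiazolidine);
* the nearly silent **E1** and the long-chain-tuned **E2** (chlorinated
  and unsaturated C10+ compounds);
* no carboxylic acid reaching the 50 spikes/s excitatory criterion on any
  sensillum.

Response entries are *measured* reference-dose rates (the 500 ms
baseline-subtracted window statistic); the profile builder converts them
to saturating evoked amplitudes by dividing out the Hill occupancy at the
reference dose and the window-average of the temporal kernel, so a
simulated replicate protocol reproduces the configured table in
expectation.  Spontaneous baselines are not reported for the real
preparations and are package assumptions (see docs/methods.md).

All remaining odorant-sensillum pairs receive small sub-criterion rates
(uniform on [0, 12) spikes/s from a fixed preset seed), below the
15 spikes/s non-responder line on average.
"""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd

from .panel import PANEL, SENSILLA
from .synth import ResponseProfile

REFERENCE_DOSE = -2.0  # log10 v/v, i.e. the 1:100 dilution

#: spontaneous firing assumptions (spikes/s) per sensillum type
BASELINE_RATES = {"Da": 20.0, "Db": 25.0, "Dg": 20.0, "C": 15.0, "E1": 5.0, "E2": 8.0}

_STRONG = {
    "Da": {
        "nonanal": 248.5, "octanal": 135.0, "decanal": 74.0,
        "heptanal": 92.0, "hexanal": 101.0, "pentanal": 61.0,
        "cis-2-hexen-1-ol": 120.0, "trans-2-hexen-1-ol": 125.0,
        "1-chlorohexane": 136.0, "pyridine": 55.0,
    },
    "Db": {
        "nonanal": 213.0, "octanal": 200.0, "heptanal": 140.0,
        "hexanal": 120.0, "pentanal": 90.0, "butanal": 75.0,
        "propanal": 70.0, "decanal": 85.0, "benzaldehyde": 55.0,
        "2-pentanone": 102.0, "3-pentanone": 122.0, "2-hexanone": 138.0,
        "2-decanone": 100.0, "2-butanone": 52.0, "2-heptanone": 60.0,
        "1-chloroheptane": 146.0, "1-chlorohexane": 131.0,
        "1-hexanol": 65.0, "1-octen-3-ol": 70.0, "2-ethyl-1-hexanol": 55.0,
        "cis-2-hexen-1-ol": 80.0, "trans-2-hexen-1-ol": 78.0,
        "ethylbenzene": 60.0, "propylbenzene": 55.0, "styrene": 50.0,
    },
    "Dg": {
        "nonanal": 223.0, "octanal": 162.0, "decanal": 108.0,
        "heptanal": 115.0, "hexanal": 110.0, "pentanal": 70.0,
        "butanal": 52.0, "sulcatone": 226.0, "2-hexanone": 111.0,
        "ethylbenzene": 90.0, "propylbenzene": 85.0, "toluene": 60.0,
        "cis-2-hexen-1-ol": 30.0, "trans-2-hexen-1-ol": 32.0,
    },
    "C": {
        "ammonia": 200.0, "propylamine": 195.0, "butylamine": 144.0,
        "1-methylpiperazine": 176.0, "thiazolidine": 130.0,
    },
    "E1": {"octanal": 30.0, "methyl tridecanoate": 23.0},
    "E2": {
        # the strongest acid stays just under the excitatory criterion
        "pentadecanoic acid": 45.0, "1-tetradecene": 60.0,
        "lauroyl chloride": 58.8, "1-chlorododecane": 57.0,
        "hexadecane": 35.0, "1-hexadecene": 42.0,
        "methyl tridecanoate": 31.0, "1-chlorotetradecane": 39.0,
        "1-chlorohexadecane": 20.0,
    },
}

# structurally twin alcohols share near-identical profiles everywhere, so
# they pair up first in the cluster tree
_TWIN_WEAK = {
    ("cis-2-hexen-1-ol", "C"): 4.0, ("trans-2-hexen-1-ol", "C"): 5.0,
    ("cis-2-hexen-1-ol", "E1"): 2.0, ("trans-2-hexen-1-ol", "E1"): 2.0,
    ("cis-2-hexen-1-ol", "E2"): 4.0, ("trans-2-hexen-1-ol", "E2"): 5.0,
}

#: odorants with an explicitly assigned temporal kernel; everything else
#: defaults to phasic (brief onset burst)
_KERNELS = {
    "pentanal": "tonic", "hexanal": "tonic", "heptanal": "tonic",
    "octanal": "tonic", "nonanal": "tonic", "sulcatone": "tonic",
    "ammonia": "tonic", "propylamine": "tonic", "butylamine": "tonic",
    "1-methylpiperazine": "tonic", "thiazolidine": "tonic",
    "cis-2-hexen-1-ol": "tonic", "trans-2-hexen-1-ol": "tonic",
    "propanal": "phasic", "butanal": "phasic", "decanal": "phasic",
}


def default_archetypes() -> dict:
    """Editable archetype configuration for the full 104-odorant panel."""
    return copy.deepcopy(
        {
            "reference_dose": REFERENCE_DOSE,
            "baseline_rates": dict(BASELINE_RATES),
            "responses": _STRONG,
            "twin_overrides": {f"{od}|{s}": v for (od, s), v in _TWIN_WEAK.items()},
            "kernels": dict(_KERNELS),
            "default_kernel": "phasic",
            "phasic_decay_constant": 0.3,
            "ec50_dose": -3.0,
            "hill_coefficient": 1.0,
            "weak_response_max": 12.0,
            "weak_seed": 20151102,
            "panel": dict(PANEL),
        }
    )


def small_archetypes(n_replicates_hint: int = 2) -> dict:
    """A 16-odorant subset preset for demos and fast pipeline runs."""
    keep = [
        "nonanal", "octanal", "hexanal", "decanal",
        "ammonia", "propylamine",
        "cis-2-hexen-1-ol", "trans-2-hexen-1-ol",
        "acetic acid", "decanoic acid",
        "sulcatone", "ethylbenzene", "thiazolidine",
        "1-tetradecene", "methyl tridecanoate", "urea",
    ]
    cfg = default_archetypes()
    cfg["panel"] = {od: PANEL[od] for od in keep}
    return cfg


def _window_kernel_mean(kernel: str, phasic_tau: float, window: float = 0.5) -> float:
    """Mean of the temporal kernel over the 500 ms response window."""
    if kernel == "tonic":
        return 1.0
    return phasic_tau / window * (1.0 - np.exp(-window / phasic_tau))


def _hill_occupancy(cfg: dict, dose: float) -> float:
    return 1.0 / (
        1.0 + 10.0 ** (cfg["hill_coefficient"] * (cfg["ec50_dose"] - dose))
    )


def configured_rate_table(cfg: dict) -> pd.DataFrame:
    """Expected reference-dose rates (spikes/s) for every panel cell.

    This is the generator's ground truth: the mean the replicate protocol
    converges to at the reference dose.
    """
    odorants = sorted(cfg["panel"])
    rng = np.random.default_rng(cfg["weak_seed"])
    table = pd.DataFrame(index=odorants, columns=list(SENSILLA), dtype=float)
    # weak rates are drawn for the full panel in a fixed order so a subset
    # preset sees the same values as the full one
    full = sorted(PANEL)
    weak = {
        (od, s): rng.uniform(0.0, cfg["weak_response_max"])
        for od in full
        for s in SENSILLA
    }
    for od in odorants:
        for s in SENSILLA:
            v = cfg["responses"].get(s, {}).get(od)
            if v is None:
                v = cfg["twin_overrides"].get(f"{od}|{s}", weak[(od, s)])
            table.loc[od, s] = v
    return table


def reference_matrix(cfg: dict | None = None):
    """The configured rate table wrapped as a noise-free ResponseMatrix."""
    from .tuning import ResponseMatrix

    cfg = cfg or default_archetypes()
    mean = configured_rate_table(cfg)
    zeros = mean * 0.0
    n = (zeros + 6).astype(int)
    classes = pd.Series({od: cfg["panel"][od] for od in mean.index})
    return ResponseMatrix(mean, zeros, n, classes, dose="1:100 v/v")


def build_profiles(cfg: dict | None = None):
    """Materialize ResponseProfiles (+ class map) from a preset config.

    The saturating evoked amplitude of each profile is chosen so that the
    expected measured rate at the reference dose equals the configured
    table entry: ``A = rate / (occupancy(reference) * window_kernel_mean)``.
    """
    cfg = cfg or default_archetypes()
    table = configured_rate_table(cfg)
    occupancy = _hill_occupancy(cfg, cfg["reference_dose"])
    tau = cfg["phasic_decay_constant"]
    profiles = []
    for od in table.index:
        kernel = cfg["kernels"].get(od, cfg["default_kernel"])
        kmean = _window_kernel_mean(kernel, tau)
        for s in SENSILLA:
            rate = float(table.loc[od, s])
            profiles.append(
                ResponseProfile(
                    sensillum_type=s,
                    odorant_id=od,
                    baseline_rate=cfg["baseline_rates"][s],
                    max_evoked_rate=rate / (occupancy * kmean),
                    kernel=kernel,
                    phasic_decay_constant=tau if kernel == "phasic" else None,
                    ec50_dose=cfg["ec50_dose"],
                    hill_coefficient=cfg["hill_coefficient"],
                )
            )
    classes = {od: cfg["panel"][od] for od in table.index}
    return profiles, classes


#: oocyte receptor/ligand presets: (receptor, ligand, EC50 in M)
OOCYTE_PRESETS = (
    ("ClOr1/Orco", "nonanal", 5.186e-7),
    ("ClOr1/Orco", "octanal", 3.398e-6),
    ("ClOr2/Orco", "decanal", 6.424e-6),
)

#: decadic molar dose grid used in the voltage-clamp dose series
OOCYTE_DOSES = tuple(10.0 ** np.arange(-9, -3))
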