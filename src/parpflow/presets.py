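"""Named parameter presets and the standard experimental designs.

Presets carry the global-fit point estimates for wild-type PARP1, the four
DNA-binding-domain deletions, the W589A point mutant, and the wild-type
measurement against intact plasmid competitor.  Wild-type and the Zn
deletions release DNA through the ternary-complex pathway; the WGR deletion
and W589A lose that pathway and release DNA at a competitor-independent rate.

For the ternary presets the probe off-rate ``k_m1`` is only bounded above
(< 10 s^-1) by the association experiment; simulations use 5 s^-1, the middle
of the admissible range (configurable via ``RateParameters.evolve``).

The plasmid preset stores the per-site ``k2`` fitted under the maximal
450-sites-per-plasmid assumption; :func:`parpflow.models.per_site_rescale`
converts to other site counts.
"""

from __future__ import annotations

from .models import CompetitorSpec, RateParameters, Scheme
from .simulate import (
    AnisotropyCalibration,
    association_instrument,
    dissociation_instrument,
)

__all__ = [
    "PRESETS",
    "PRESET_DISSOCIATION_SCHEME",
    "PLASMID_SITES_RANGE",
    "DEFAULT_PLASMID_SITES",
    "get_preset",
    "association_design",
    "dissociation_design",
]

KM1_TERNARY_DEFAULT = 5.0  # s^-1; association data only bound it below 10

PRESETS = {
    "WT": RateParameters(
        k1=3.1, k_m1=KM1_TERNARY_DEFAULT, k2=0.043, k_m2=102.0, k3=9.7, k_m3=0.013
    ),
    "dZn1": RateParameters(
        k1=3.7, k_m1=KM1_TERNARY_DEFAULT, k2=0.018, k_m2=97.0, k3=21.0, k_m3=0.027
    ),
    "dZn2": RateParameters(
        k1=4.0, k_m1=KM1_TERNARY_DEFAULT, k2=0.073, k_m2=145.0, k3=15.0, k_m3=0.023
    ),
    "dZn3": RateParameters(
        k1=5.5, k_m1=KM1_TERNARY_DEFAULT, k2=0.034, k_m2=76.0, k3=19.0, k_m3=0.050
    ),
    "dWGR": RateParameters(k1=2.4, k_m1=18.7),
    "W589A": RateParameters(k1=4.2, k_m1=20.2),
    "WT-plasmid": RateParameters(
        k1=3.1, k_m1=KM1_TERNARY_DEFAULT, k2=0.041, k_m2=161.0, k3=9.0, k_m3=0.032
    ),
}

#: Dissociation mechanism each construct follows.
PRESET_DISSOCIATION_SCHEME = {
    "WT": Scheme.TERNARY,
    "dZn1": Scheme.TERNARY,
    "dZn2": Scheme.TERNARY,
    "dZn3": Scheme.TERNARY,
    "dWGR": Scheme.SIMPLE_COMPETITION,
    "W589A": Scheme.SIMPLE_COMPETITION,
    "WT-plasmid": Scheme.TERNARY,
}

#: Admissible binding sites per 4.5 kb plasmid: at least 5 (5 nM plasmid
#: strips a 25 nM probe complex), at most ~450 (one protein per 10 bp).
PLASMID_SITES_RANGE = (5, 450)
DEFAULT_PLASMID_SITES = 200

_ALIASES = {"ΔWGR".lower(): "dWGR", "ΔZn1".lower(): "dZn1",
            "ΔZn2".lower(): "dZn2", "ΔZn3".lower(): "dZn3"}


def get_preset(name: str) -> RateParameters:
    key = name if name in PRESETS else _ALIASES.get(name.lower())
    if key is None:
        lookup = {k.lower(): k for k in PRESETS}
        key = lookup.get(name.lower())
    if key is None:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {', '.join(PRESETS)}"
        )
    return PRESETS[key]


def canonical_preset_name(name: str) -> str:
    get_preset(name)
    key = name if name in PRESETS else _ALIASES.get(name.lower())
    if key is None:
        key = {k.lower(): k for k in PRESETS}[name.lower()]
    return key


def association_design(seed: int = 0, **instrument_kw) -> dict:
    """Standard association design: 30 nM probe mixed with 60-250 nM protein,
    followed for 25 ms."""
    return {
        "p_concs": [60.0, 83.0, 110.0, 150.0, 200.0, 250.0],
        "dstar_total": 30.0,
        "instrument": association_instrument(seed=seed, **instrument_kw),
        "calibration": AnisotropyCalibration(),
    }


def dissociation_design(preset_name: str, seed: int = 0, *,
                        plasmid_sites: int = DEFAULT_PLASMID_SITES,
                        **instrument_kw) -> dict:
    """Standard dissociation design for a construct.

    37 nM protein pre-bound to 25 nM probe, mixed with competitor.  Ternary
    constructs use the six-concentration oligomer series spanning 76 nM-4 uM;
    the simple-competition mutants the 0.4/1.3/4 uM series over 1 s; the
    plasmid design 0.7/2.0/5.8 nM particles.
    """
    key = canonical_preset_name(preset_name)
    scheme = PRESET_DISSOCIATION_SCHEME[key]
    if key == "WT-plasmid":
        competitors = [CompetitorSpec(c, plasmid_sites) for c in (0.7, 2.0, 5.8)]
        t_end = 5.0
    elif scheme is Scheme.TERNARY:
        competitors = [76.0, 149.0, 225.0, 398.0, 1000.0, 4000.0]
        t_end = 5.0
    else:
        competitors = [400.0, 1300.0, 4000.0]
        t_end = 1.0
    t_end = instrument_kw.pop("t_end", t_end)
    return {
        "pre_p": 37.0,
        "pre_dstar": 25.0,
        "competitors": competitors,
        "scheme": scheme,
        "instrument": dissociation_instrument(seed=seed, t_end=t_end, **instrument_kw),
        "calibration": AnisotropyCalibration(),
    }
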