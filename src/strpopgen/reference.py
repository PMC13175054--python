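"""Reference summary values for the Korean national cattle parentage panel.

The 11-microsatellite panel used for Hanwoo parentage testing has
well-known published per-locus summary statistics (allele counts,
heterozygosities, polymorphic information content, inbreeding
coefficients) and per-locus non-exclusion probabilities for the national
cow population.  The per-animal genotypes behind them are not public, but
the printed per-locus values are themselves useful inputs: the summary
mean row and the combined (product) non-exclusion probabilities can be
reconstructed from them, which is exactly what the worked examples and the
acceptance checks do.

Values are stored at their printed precision (3-4 decimals).
"""

from __future__ import annotations

import pandas as pd

#: per-locus diversity summary of the national cow population
#: columns: k (allele count), n, h_obs, h_exp, pic, f_is
PANEL_DIVERSITY: dict[str, dict[str, float]] = {
    "BM1824":  {"k": 11, "n": 778544, "h_obs": 0.732, "h_exp": 0.730, "pic": 0.684, "f_is": -0.0038},
    "BM2113":  {"k": 17, "n": 778544, "h_obs": 0.736, "h_exp": 0.733, "pic": 0.692, "f_is": -0.0034},
    "ETH10":   {"k": 12, "n": 778544, "h_obs": 0.780, "h_exp": 0.778, "pic": 0.745, "f_is": -0.0020},
    "ETH225":  {"k": 11, "n": 778544, "h_obs": 0.693, "h_exp": 0.691, "pic": 0.649, "f_is": -0.0022},
    "ETH3":    {"k": 15, "n": 778544, "h_obs": 0.764, "h_exp": 0.763, "pic": 0.723, "f_is": -0.0017},
    "INRA023": {"k": 16, "n": 778544, "h_obs": 0.788, "h_exp": 0.784, "pic": 0.755, "f_is": -0.0040},
    "SPS115":  {"k": 15, "n": 778544, "h_obs": 0.727, "h_exp": 0.724, "pic": 0.683, "f_is": -0.0040},
    "TGLA122": {"k": 28, "n": 778544, "h_obs": 0.846, "h_exp": 0.843, "pic": 0.825, "f_is": -0.0028},
    "TGLA126": {"k": 9,  "n": 778544, "h_obs": 0.669, "h_exp": 0.665, "pic": 0.625, "f_is": -0.0053},
    "TGLA227": {"k": 19, "n": 778544, "h_obs": 0.851, "h_exp": 0.849, "pic": 0.831, "f_is": -0.0024},
    "TGLA53":  {"k": 19, "n": 778544, "h_obs": 0.891, "h_exp": 0.890, "pic": 0.880, "f_is": -0.0014},
}

#: per-locus non-exclusion probabilities for the same population
PANEL_EXCLUSION: dict[str, dict[str, float]] = {
    "BM1824":  {"ne_1p": 0.681, "ne_2p": 0.507, "ne_pp": 0.324, "ne_i": 0.118, "ne_si": 0.415},
    "BM2113":  {"ne_1p": 0.670, "ne_2p": 0.493, "ne_pp": 0.305, "ne_i": 0.112, "ne_si": 0.411},
    "ETH10":   {"ne_1p": 0.608, "ne_2p": 0.429, "ne_pp": 0.245, "ne_i": 0.082, "ne_si": 0.381},
    "ETH225":  {"ne_1p": 0.719, "ne_2p": 0.542, "ne_pp": 0.353, "ne_i": 0.138, "ne_si": 0.439},
    "ETH3":    {"ne_1p": 0.641, "ne_2p": 0.463, "ne_pp": 0.283, "ne_i": 0.096, "ne_si": 0.393},
    "INRA023": {"ne_1p": 0.588, "ne_2p": 0.409, "ne_pp": 0.221, "ne_i": 0.075, "ne_si": 0.377},
    "SPS115":  {"ne_1p": 0.679, "ne_2p": 0.502, "ne_pp": 0.314, "ne_i": 0.117, "ne_si": 0.417},
    "TGLA122": {"ne_1p": 0.479, "ne_2p": 0.311, "ne_pp": 0.140, "ne_i": 0.043, "ne_si": 0.339},
    "TGLA126": {"ne_1p": 0.741, "ne_2p": 0.563, "ne_pp": 0.372, "ne_i": 0.152, "ne_si": 0.455},
    "TGLA227": {"ne_1p": 0.467, "ne_2p": 0.302, "ne_pp": 0.133, "ne_i": 0.041, "ne_si": 0.336},
    "TGLA53":  {"ne_1p": 0.366, "ne_2p": 0.223, "ne_pp": 0.078, "ne_i": 0.022, "ne_si": 0.311},
}

#: reported combined (all-marker product) non-exclusion probabilities
PANEL_EXCLUSION_COMBINED: dict[str, float] = {
    "ne_1p": 0.003086,
    "ne_2p": 6.51e-05,
    "ne_pp": 9.00e-08,
    "ne_i": 7.60e-13,
    "ne_si": 2.84e-05,
}


def panel_diversity_frame() -> pd.DataFrame:
    """Per-locus diversity reference values as a DataFrame (panel order)."""
    df = pd.DataFrame.from_dict(PANEL_DIVERSITY, orient="index")
    df.index.name = "locus"
    return df


def panel_exclusion_frame() -> pd.DataFrame:
    """Per-locus non-exclusion reference values as a DataFrame."""
    df = pd.DataFrame.from_dict(PANEL_EXCLUSION, orient="index")
    df.index.name = "locus"
    return df
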