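"""Canonical naming and ordering of the 264-parameter texture bank.

Feature names follow the MaZda convention: co-occurrence features are
``S(dx,dy)<Feature>`` where (dx, dy) is the pixel-pair offset with dx the
column displacement and dy the *upward* row displacement, so (d,0) is the
0-degree direction, (d,d) 45 degrees, (0,d) 90 degrees and (d,-d)
135 degrees.  Run-length features carry a direction prefix (Horzl_, Vertl_,
45dgr_, 135dr_).

Group cardinalities: 11 histogram + 4 gradient + 220 co-occurrence
(5 distances x 4 directions x 11 features) + 20 run-length (4 directions x
5 features) + 4 wavelet + 5 autoregressive = 264.
"""

from __future__ import annotations

HISTOGRAM_FEATURES = (
    "Mean", "Variance", "Skewness", "Kurtosis",
    "Perc01", "Perc10", "Perc25", "Perc50", "Perc75", "Perc90", "Perc99",
)
HISTOGRAM_PERCENTILES = (1, 10, 25, 50, 75, 90, 99)

GRADIENT_FEATURES = ("GrMean", "GrVariance", "GrSkewness", "GrKurtosis")

GLCM_FEATURES = (
    "AngScMom", "Contrast", "Correlat", "SumOfSqs", "InvDfMom",
    "SumAverg", "SumVarnc", "SumEntrp", "Entropy", "DifVarnc", "DifEntrp",
)
GLCM_DISTANCES = (1, 2, 3, 4, 5)


def glcm_offsets() -> list[tuple[int, int]]:
    """All 20 (dx, dy) offsets: distances 1..5 x directions 0/45/90/135 deg."""
    out = []
    for d in GLCM_DISTANCES:
        out.extend([(d, 0), (d, d), (0, d), (d, -d)])
    return out


def glcm_name(dx: int, dy: int, feature: str) -> str:
    return f"S({dx},{dy}){feature}"


RLM_FEATURES = ("ShrtREmph", "LngREmph", "GLevNonUni", "RLNonUni", "Fraction")
RLM_DIRECTIONS = ("Horzl", "Vertl", "45dgr", "135dr")


def rlm_name(direction: str, feature: str) -> str:
    return f"{direction}_{feature}"


WAVELET_FEATURES = ("WavEnLL", "WavEnLH", "WavEnHL", "WavEnHH")
AR_FEATURES = ("Teta1", "Teta2", "Teta3", "Teta4", "Sigma")


def _build_names() -> tuple[tuple[str, ...], dict[str, str]]:
    names: list[str] = []
    groups: dict[str, str] = {}
    for f in HISTOGRAM_FEATURES:
        names.append(f)
        groups[f] = "histogram"
    for f in GRADIENT_FEATURES:
        names.append(f)
        groups[f] = "gradient"
    for dx, dy in glcm_offsets():
        for f in GLCM_FEATURES:
            n = glcm_name(dx, dy, f)
            names.append(n)
            groups[n] = "glcm"
    for d in RLM_DIRECTIONS:
        for f in RLM_FEATURES:
            n = rlm_name(d, f)
            names.append(n)
            groups[n] = "rlm"
    for f in WAVELET_FEATURES:
        names.append(f)
        groups[f] = "wavelet"
    for f in AR_FEATURES:
        names.append(f)
        groups[f] = "ar"
    return tuple(names), groups


FEATURE_NAMES, FEATURE_GROUPS = _build_names()

GROUP_SIZES = {
    "histogram": 11,
    "gradient": 4,
    "glcm": 220,
    "rlm": 20,
    "wavelet": 4,
    "ar": 5,
}

N_FEATURES = 264
assert len(FEATURE_NAMES) == N_FEATURES
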