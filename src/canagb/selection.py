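"""Sensitivity screening, collinearity pruning, and feature-scheme assembly.

The two-stage screen mirrors the study workflow for reducing 159 spectral and
954 texture candidates to compact predictor sets:

1. **Sensitivity screen** — Pearson correlation of every feature with AGB
   (pairwise-complete over samples); keep features with ``|r|`` at or above a
   threshold (default 0.6), ordered by descending ``|r|``.
2. **Collinearity prune** — a greedy pass over that ordering accepts a feature
   iff its absolute correlation with every already-accepted feature stays
   below an inter-feature threshold (default 0.9).  Ties in ``|r|`` break
   alphabetically, making the outcome deterministic.

Three schemes are assembled: ``spectra`` (pruned band + VI features),
``texture`` (pruned texture features), and ``spectra_texture`` (their
concatenation).  The module also ships the reference variable sets reported
for the original winter-canola field campaign (8 spectral + 23 texture
variables), usable as fixed schemes; the published spellings DNCI and MTCAI
are treated as aliases of DCNI and MTCI.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvariantViolationError
from .spectral import VI_ALIASES, get_vi_registry
from .texture import TEXTURE_STATS

__all__ = [
    "FeatureScheme",
    "REFERENCE_SPECTRA_VARIABLES",
    "REFERENCE_TEXTURE_VARIABLES",
    "feature_group",
    "correlate",
    "screen",
    "prune_collinear",
    "build_schemes",
    "reference_schemes",
]

logger = logging.getLogger(__name__)

#: Spectral variables selected in the original field campaign (8), with the
#: published alias spellings resolved (DNCI -> DCNI, MTCAI -> MTCI).
REFERENCE_SPECTRA_VARIABLES: tuple[str, ...] = (
    "Band_498", "Band_502", "Band_734", "DCNI", "MSR", "MTCI", "CI", "TCARI",
)

#: Texture variables selected in the original field campaign (23).
REFERENCE_TEXTURE_VARIABLES: tuple[str, ...] = (
    "CON_686", "CON_698", "CON_678", "CON_670", "CON_662",
    "ENT_482", "ENT_494", "ENT_470", "ASM_534",
    "VOGREI3_CON", "OSAVI_DIS", "OSAVI_HOM",
    "MNDVI_COR", "SRVI2_COR", "ARVI_COR", "TCARI_COR", "NDVI_COR",
    "NDRE_COR", "DCNI_COR", "NDI_COR", "VOGREI3_COR", "WDRVI_COR", "NDVI_ASM",
)


@dataclass(frozen=True)
class FeatureScheme:
    """A named, ordered subset of feature columns."""

    name: str
    features: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.features)


_BAND_RE = re.compile(r"^Band_\d+$")
_BAND_TEXTURE_RE = re.compile(r"^(" + "|".join(TEXTURE_STATS) + r")_\d+$")


def feature_group(name: str) -> str:
    """Classify a feature column: narrowband | VI | band-texture | VI-texture."""
    if _BAND_RE.match(name):
        return "narrowband"
    if _BAND_TEXTURE_RE.match(name):
        return "band-texture"
    vi_names = set(get_vi_registry()) | set(VI_ALIASES)
    base = name.rsplit("_", 1)
    if len(base) == 2 and base[1] in TEXTURE_STATS and base[0] in vi_names:
        return "VI-texture"
    if name in vi_names:
        return "VI"
    return "other"


def correlate(
    table: pd.DataFrame,
    response: str = "agb",
    features: Sequence[str] | None = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pearson correlation of every feature with the response.

    NaNs are excluded pairwise per feature.  Features with fewer than
    ``min_pairs`` complete pairs or zero variance get ``r = NaN`` and a flag.

    Returns a DataFrame with columns feature, group, r, abs_r, n, flag.
    """
    if response not in table.columns:
        raise InvalidArgumentError(f"response column {response!r} missing")
    if features is None:
        features = [c for c in table.columns if c != response]
    y_all = table[response].to_numpy(dtype=float)
    records = []
    for name in features:
        x_all = table[name].to_numpy(dtype=float)
        ok = np.isfinite(x_all) & np.isfinite(y_all)
        n = int(ok.sum())
        flag = ""
        r = np.nan
        if n < min_pairs:
            flag = "too-few-pairs"
        else:
            x, y = x_all[ok], y_all[ok]
            if x.std() == 0 or y.std() == 0:
                flag = "zero-variance"
            else:
                r = float(np.corrcoef(x, y)[0, 1])
        records.append(
            {
                "feature": name,
                "group": feature_group(name),
                "r": r,
                "abs_r": abs(r) if np.isfinite(r) else np.nan,
                "n": n,
                "flag": flag,
            }
        )
    return pd.DataFrame.from_records(records)


def screen(report: pd.DataFrame, threshold: float = 0.6) -> list[str]:
    """Features with ``|r| >= threshold``, ordered by descending ``|r|``
    (alphabetical tie-break).  Flagged features are never retained."""
    if not 0.0 < threshold < 1.0:
        raise InvalidArgumentError("screening threshold must lie in (0, 1)")
    ok = report[(report["flag"] == "") & (report["abs_r"] >= threshold)]
    ok = ok.sort_values(["abs_r", "feature"], ascending=[False, True], kind="mergesort")
    return list(ok["feature"])


def prune_collinear(
    table: pd.DataFrame,
    retained: Sequence[str],
    inter_threshold: float = 0.9,
) -> list[str]:
    """Greedy collinearity prune over a ``|r|``-descending candidate list:
    accept a feature iff its absolute pairwise correlation with every feature
    accepted so far is below ``inter_threshold``."""
    if not retained:
        return []
    corr = table[list(retained)].corr(method="pearson")  # pairwise-complete
    accepted: list[str] = []
    for name in retained:
        inter = corr.loc[name, accepted].abs() if accepted else pd.Series(dtype=float)
        if (inter.fillna(0.0) < inter_threshold).all():
            accepted.append(name)
    return accepted


def build_schemes(
    spectral_features: Sequence[str], texture_features: Sequence[str]
) -> dict[str, FeatureScheme]:
    """Assemble the spectra, texture, and combined spectra-texture schemes."""
    overlap = set(spectral_features) & set(texture_features)
    if overlap:
        raise InvariantViolationError(
            f"feature name collision across schemes: {sorted(overlap)}"
        )
    spectra = FeatureScheme("spectra", tuple(spectral_features))
    texture = FeatureScheme("texture", tuple(texture_features))
    combined = FeatureScheme("spectra_texture", spectra.features + texture.features)
    return {"spectra": spectra, "texture": texture, "spectra_texture": combined}


def reference_schemes() -> dict[str, FeatureScheme]:
    """The fixed 8 + 23 = 31-variable schemes reported for the original field
    campaign (usable when reproducing its scheme structure on synthetic data)."""
    return build_schemes(REFERENCE_SPECTRA_VARIABLES, REFERENCE_TEXTURE_VARIABLES)


def save_schemes(schemes: Mapping[str, FeatureScheme], path: str | Path) -> Path:
    path = Path(path)
    payload = [
        {"name": s.name, "features": list(s.features)} for s in schemes.values()
    ]
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_schemes(path: str | Path) -> dict[str, FeatureScheme]:
    payload = json.loads(Path(path).read_text())
    return {
        entry["name"]: FeatureScheme(entry["name"], tuple(entry["features"]))
        for entry in payload
    }
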