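"""2D and 3D texture indices built from selected texture features.

Six index families combine two (2D) or three (3D) GLCM texture features
T1, T2, T3 drawn from any bands:

    NDTI  = (T1 - T2) / (T1 + T2)          DTI  = T1 - T2
    RTI   = T1 / T2
    NDTTI = (T1 - T2 - T3) / (T1 + T2 + T3)
    DTTI  = T1 - T2 - T3                   RTTI = T1 / (T2 * T3)

Candidates are enumerated exhaustively over a selected texture-feature
pool (ordered head, with the T2 <-> T3 symmetry of the 3D families
deduplicated) and ranked by the magnitude of their Pearson correlation
with LAI, keeping only significant candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats

INDEX_TYPES_2D = ("NDTI", "DTI", "RTI")
INDEX_TYPES_3D = ("NDTTI", "DTTI", "RTTI")
INDEX_TYPES = INDEX_TYPES_2D + INDEX_TYPES_3D

#: texture features retained for index construction in the replication
#: configuration: B-band var/mean/con/dis/cor, R-band var/con/dis,
#: NIR-band cor, G-band con
DEFAULT_TF_POOL = (
    "B_var", "B_mean", "B_con", "B_dis", "B_cor",
    "R_var", "R_con", "R_dis", "NIR_cor", "G_con",
)


@dataclass(frozen=True)
class TextureIndexSpec:
    index_type: str
    components: tuple[str, ...]

    def __post_init__(self):
        if self.index_type not in INDEX_TYPES:
            raise ValueError(f"unknown index type {self.index_type!r}")
        need = 2 if self.index_type in INDEX_TYPES_2D else 3
        if len(self.components) != need:
            raise ValueError(
                f"{self.index_type} needs {need} components, got {len(self.components)}"
            )
        if len(set(self.components)) != len(self.components):
            raise ValueError("components must be distinct")

    @property
    def name(self) -> str:
        return f"{self.index_type}({','.join(self.components)})"


@dataclass(frozen=True)
class RankedIndex:
    spec: TextureIndexSpec
    r: float
    p_value: float


def evaluate_index(spec: TextureIndexSpec, tf_values) -> np.ndarray:
    """Per-sample index values; zero denominators become NaN (missing)."""
    if isinstance(tf_values, pd.DataFrame):
        cols = {c: tf_values[c].to_numpy(dtype=float) for c in spec.components}
    else:
        cols = {c: np.atleast_1d(np.asarray(tf_values[c], dtype=float)) for c in spec.components}
    t = [cols[c] for c in spec.components]
    kind = spec.index_type
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "NDTI":
            num, den = t[0] - t[1], t[0] + t[1]
        elif kind == "DTI":
            return t[0] - t[1]
        elif kind == "RTI":
            num, den = t[0], t[1]
        elif kind == "NDTTI":
            num, den = t[0] - t[1] - t[2], t[0] + t[1] + t[2]
        elif kind == "DTTI":
            return t[0] - t[1] - t[2]
        elif kind == "RTTI":
            num, den = t[0], t[1] * t[2]
        out = num / den
    return np.where(np.abs(den) < 1e-300, np.nan, out)


def enumerate_candidates(
    selected_tf_names,
    index_types=INDEX_TYPES,
) -> list[TextureIndexSpec]:
    """All distinct component assignments per requested index family.

    2D families enumerate ordered pairs; 3D families enumerate an ordered
    head T1 with an unordered tail {T2, T3} because all three 3D formulas
    are symmetric under T2 <-> T3.
    """
    names = list(selected_tf_names)
    specs: list[TextureIndexSpec] = []
    for kind in index_types:
        if kind in INDEX_TYPES_2D:
            if len(names) < 2:
                raise ValueError("need >= 2 texture features for 2D indices")
            specs.extend(TextureIndexSpec(kind, pair) for pair in permutations(names, 2))
        else:
            if len(names) < 3:
                raise ValueError("need >= 3 texture features for 3D indices")
            for head in names:
                rest = [n for n in names if n != head]
                for tail in combinations(rest, 2):
                    specs.append(TextureIndexSpec(kind, (head, *tail)))
    return specs


def select_top_indices(
    candidates: list[TextureIndexSpec],
    feature_table: pd.DataFrame,
    lai,
    k: int = 10,
    alpha: float = 0.05,
) -> list[RankedIndex]:
    """Rank candidates by |Pearson r| with LAI and keep the top ``k``.

    Candidates that are constant, have fewer than 3 non-missing samples or
    fail the significance test (p >= alpha) are dropped.  Ties in |r| are
    broken lexicographically by (index_type, components).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    y = np.asarray(lai, dtype=float)
    if len(y) != len(feature_table):
        raise ValueError("lai length must match feature table")
    ranked: list[RankedIndex] = []
    for spec in candidates:
        vals = evaluate_index(spec, feature_table)
        ok = np.isfinite(vals) & np.isfinite(y)
        if ok.sum() < 3 or np.std(vals[ok]) == 0:
            continue
        r, p = stats.pearsonr(vals[ok], y[ok])
        if not np.isfinite(r) or p >= alpha:
            continue
        ranked.append(RankedIndex(spec, float(r), float(p)))
    if not ranked:
        raise ValueError("no candidate index is defined and significant")
    ranked.sort(key=lambda c: (-abs(c.r), c.spec.index_type, c.spec.components))
    return ranked[:k]


def index_feature_frame(specs: list[TextureIndexSpec], tf_table: pd.DataFrame) -> pd.DataFrame:
    """Evaluate a list of index specs into named feature columns."""
    return pd.DataFrame(
        {s.name: evaluate_index(s, tf_table) for s in specs}, index=tf_table.index
    )
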