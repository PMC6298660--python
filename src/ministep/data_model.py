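"""Panel data containers, BMI category coding, and descriptive statistics.

The observed data object is a :class:`WavePanel`: a directed friendship
network (binary adjacency, no self-ties) plus an ordinal BMI category per
actor, observed at two or more waves. BMI in kg/m^2 is collapsed onto an
11-level ordinal scale (cut points 19, 20, ..., 26, 28, 31) and modelled
after mean-centering, so the dynamics operate on a bounded integer scale
while retaining ordering information.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BMI_CUT_POINTS",
    "N_CATEGORIES",
    "CATEGORY_LABELS",
    "BehaviorScale",
    "Wave",
    "WavePanel",
    "CovariateTable",
    "code_bmi",
    "center_behavior",
    "read_panel",
    "write_panel",
    "descriptives",
]

#: Upper-boundary cut points of the 11 ordinal BMI categories.
BMI_CUT_POINTS = np.array([19, 20, 21, 22, 23, 24, 25, 26, 28, 31], dtype=float)

N_CATEGORIES = 11

#: Human-readable kg/m^2 band for each category code 1..11.
CATEGORY_LABELS = [
    "<19",
    "19 to 19.99",
    "20 to 20.99",
    "21 to 21.99",
    "22 to 22.99",
    "23 to 23.99",
    "24 to 24.99",
    "25 to 25.99",
    "26 to 27.99",
    "28 to 30.99",
    ">=31",
]

RACE_CATEGORIES = ("White", "Black", "Hispanic", "Other")


def code_bmi(bmi):
    """Map BMI in kg/m^2 to the ordinal category code 1..11.

    BMI below 19 is code 1; integer-truncated BMI 19..25 gives codes 2..8;
    [26, 28) is 9; [28, 31) is 10; >= 31 is 11. Total and weakly monotone
    on (0, inf).

    Parameters
    ----------
    bmi : float or array_like
        Positive, finite BMI value(s).

    Returns
    -------
    int or ndarray of int
        Category code(s) in 1..11.
    """
    arr = np.asarray(bmi, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("BMI values must be positive and finite")
    codes = np.searchsorted(BMI_CUT_POINTS, arr, side="right") + 1
    if np.isscalar(bmi) or arr.ndim == 0:
        return int(codes)
    return codes.astype(int)


@dataclass(frozen=True)
class BehaviorScale:
    """Centering and range metadata for the ordinal behavior variable."""

    n_categories: int
    centering_constant: float
    range: float

    def center(self, codes):
        """Return centered values (``code - centering_constant``), nan-safe."""
        return np.asarray(codes, dtype=float) - self.centering_constant

    def uncenter(self, centered):
        return np.asarray(centered, dtype=float) + self.centering_constant


def center_behavior(codes):
    """Mean-center behavior codes pooled over all non-missing actor-waves.

    Parameters
    ----------
    codes : array_like
        Category codes, shape ``(n_actors,)`` or ``(n_actors, n_waves)``,
        with ``nan`` marking missing observations.

    Returns
    -------
    scale : BehaviorScale
    centered : ndarray
        Same shape as input; missing entries propagate as ``nan``.
    """
    arr = np.asarray(codes, dtype=float)
    obs = arr[~np.isnan(arr)]
    if obs.size == 0:
        raise ValueError("cannot center an all-missing behavior array")
    if np.any((obs < 1) | (obs > N_CATEGORIES)):
        raise ValueError(f"behavior codes must lie in 1..{N_CATEGORIES}")
    constant = float(obs.mean())
    centered = arr - constant
    rng = float(obs.max() - obs.min())
    scale = BehaviorScale(N_CATEGORIES, constant, rng)
    return scale, centered


@dataclass
class Wave:
    """One observation wave: directed adjacency + behavior + participation.

    ``participating`` is True for actors observed at the wave (behavior
    present); non-participants keep incoming nominations but contribute no
    outgoing ties and have ``nan`` behavior. ``bmi_raw`` holds kg/m^2
    values when the panel was built from raw anthropometry.
    """

    adjacency: np.ndarray
    behavior: np.ndarray
    participating: np.ndarray
    bmi_raw: np.ndarray | None = None

    def validate(self, n: int) -> None:
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be n x n")
        if not np.all(np.isin(self.adjacency, (0, 1))):
            raise ValueError("adjacency must be binary")
        if np.any(np.diagonal(self.adjacency) != 0):
            raise ValueError("self-ties are not allowed")
        obs = self.behavior[~np.isnan(self.behavior)]
        if np.any((obs < 1) | (obs > N_CATEGORIES)):
            raise ValueError(f"behavior codes must lie in 1..{N_CATEGORIES}")


@dataclass
class WavePanel:
    """Longitudinal panel of waves over a fixed actor set."""

    actor_ids: list[str]
    waves: list[Wave]
    wave_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.wave_labels:
            self.wave_labels = [f"T{m + 1}" for m in range(len(self.waves))]
        self.validate()

    @property
    def n_actors(self) -> int:
        return len(self.actor_ids)

    @property
    def n_waves(self) -> int:
        return len(self.waves)

    @property
    def n_periods(self) -> int:
        return len(self.waves) - 1

    def validate(self) -> None:
        if len(self.waves) < 2:
            raise ValueError("a panel needs at least two waves")
        if len(set(self.actor_ids)) != len(self.actor_ids):
            raise ValueError("actor ids must be unique")
        for wave in self.waves:
            wave.validate(self.n_actors)

    def behavior_matrix(self) -> np.ndarray:
        """Behavior codes as an ``(n_actors, n_waves)`` float array."""
        return np.column_stack([w.behavior for w in self.waves])

    def behavior_scale(self) -> BehaviorScale:
        scale, _ = center_behavior(self.behavior_matrix())
        return scale


class CovariateTable:
    """Constant actor covariates with centering metadata.

    Wraps a DataFrame indexed by actor id with columns ``male`` (0/1),
    ``race`` (one of White/Black/Hispanic/Other), ``first_year`` (0/1) and
    ``floor`` (categorical label). Derived dummies (``white``, ``hispanic``,
    ...) and centered numeric versions are exposed through :meth:`values`
    and :meth:`centered`.
    """

    DUMMY_RACES = {"white": "White", "black": "Black", "hispanic": "Hispanic"}

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        frame.index = frame.index.astype(str)
        missing = {"male", "race", "first_year", "floor"} - set(frame.columns)
        if missing:
            raise ValueError(f"covariate table is missing columns: {sorted(missing)}")
        bad = set(frame["race"].unique()) - set(RACE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown race categories: {sorted(bad)}")
        self.frame = frame

    @property
    def actor_ids(self) -> list[str]:
        return list(self.frame.index)

    def reindex(self, actor_ids) -> "CovariateTable":
        missing = set(map(str, actor_ids)) - set(self.frame.index)
        if missing:
            raise ValueError(f"covariates missing for actors: {sorted(missing)}")
        return CovariateTable(self.frame.loc[[str(a) for a in actor_ids]])

    def values(self, name: str) -> np.ndarray:
        """Raw covariate column (dummies resolved), aligned to table order."""
        if name in self.frame.columns:
            col = self.frame[name]
            if name == "race" or name == "floor":
                return col.to_numpy()
            return col.to_numpy(dtype=float)
        if name in self.DUMMY_RACES:
            return (self.frame["race"] == self.DUMMY_RACES[name]).to_numpy(dtype=float)
        raise KeyError(f"unknown covariate {name!r}")

    def centered(self, name: str) -> np.ndarray:
        """Mean-centered numeric covariate (mean taken over all actors)."""
        vals = self.values(name)
        if vals.dtype.kind not in "fiu":
            raise TypeError(f"covariate {name!r} is categorical; cannot center")
        return vals - vals.mean()

    def as_dict(self) -> dict[str, np.ndarray]:
        """All covariates (raw dummies + categoricals) keyed by name."""
        out = {
            "male": self.values("male"),
            "first_year": self.values("first_year"),
            "floor": self.values("floor"),
            "race": self.values("race"),
        }
        for dummy in self.DUMMY_RACES:
            out[dummy] = self.values(dummy)
        return out


# ---------------------------------------------------------------------------
# CSV input/output (long edge list + wide behavior table)
# ---------------------------------------------------------------------------

_EGO_NAMES = ("ego", "ego_id", "from", "source", "sender")
_ALTER_NAMES = ("alter", "alter_id", "to", "target", "receiver")
_WAVE_NAMES = ("wave", "time", "t", "phase")
_ID_NAMES = ("id", "actor", "actor_id", "participant", "participant_id")


def _find_column(columns, candidates, kind):
    lowered = {c.lower(): c for c in columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    raise ValueError(f"could not identify the {kind} column among {list(columns)}")


def read_panel(links_file, bmi_file, covariates_file=None, bmi_as="auto"):
    """Read a panel from a long edge-list CSV and a wide behavior CSV.

    The actor universe is the set of ids in the behavior file. Edge rows are
    (ego, alter, wave); behavior columns after the id column are wave labels
    in temporal order. ``bmi_as`` selects whether behavior values are raw
    kg/m^2 (``"raw"``), category codes (``"codes"``), or sniffed
    (``"auto"``: integer values within 1..11 are treated as codes).

    Returns ``(panel, covariates)``; ``covariates`` is None when no
    covariate file is given.
    """
    bmi = pd.read_csv(bmi_file)
    id_col = _find_column(bmi.columns, _ID_NAMES, "actor id")
    wave_cols = [c for c in bmi.columns if c != id_col]
    if len(wave_cols) < 2:
        raise ValueError("behavior file must contain at least two wave columns")
    actor_ids = [str(a) for a in bmi[id_col]]
    if len(set(actor_ids)) != len(actor_ids):
        raise ValueError("duplicate actor ids in behavior file")
    index = {a: k for k, a in enumerate(actor_ids)}
    n = len(actor_ids)

    values = bmi[wave_cols].to_numpy(dtype=float)
    if bmi_as == "auto":
        obs = values[~np.isnan(values)]
        is_codes = obs.size > 0 and np.all(obs == np.round(obs)) and np.all(
            (obs >= 1) & (obs <= N_CATEGORIES)
        )
    else:
        is_codes = bmi_as == "codes"
    if is_codes:
        codes, raw = values, None
    else:
        codes = np.full_like(values, np.nan)
        mask = ~np.isnan(values)
        codes[mask] = code_bmi(values[mask])
        raw = values

    links = pd.read_csv(links_file)
    ego_col = _find_column(links.columns, _EGO_NAMES, "ego")
    alter_col = _find_column(links.columns, _ALTER_NAMES, "alter")
    wave_col = _find_column(links.columns, _WAVE_NAMES, "wave")
    extra = set(links.columns) - {ego_col, alter_col, wave_col}
    if extra:
        warnings.warn(f"ignoring unrecognized link columns: {sorted(extra)}")

    wave_key = {str(label): m for m, label in enumerate(wave_cols)}
    # Accept wave labels either as the behavior column names or as 1-based integers.
    for m in range(len(wave_cols)):
        wave_key.setdefault(str(m + 1), m)

    n_dup = links.duplicated(subset=[ego_col, alter_col, wave_col]).sum()
    if n_dup:
        warnings.warn(f"dropped {n_dup} duplicate (ego, alter, wave) rows")
        links = links.drop_duplicates(subset=[ego_col, alter_col, wave_col])

    adjacency = [np.zeros((n, n), dtype=np.int8) for _ in wave_cols]
    n_self = 0
    for ego, alter, wave in links[[ego_col, alter_col, wave_col]].itertuples(index=False):
        ego, alter = str(ego), str(alter)
        if ego not in index or alter not in index:
            raise ValueError(f"unknown actor id in links file: {ego!r} -> {alter!r}")
        key = str(wave)
        if key not in wave_key:
            raise ValueError(f"unknown wave label {wave!r} in links file")
        if ego == alter:
            n_self += 1
            continue
        adjacency[wave_key[key]][index[ego], index[alter]] = 1
    if n_self:
        warnings.warn(f"dropped {n_self} self-nomination rows")

    waves = []
    for m in range(len(wave_cols)):
        waves.append(
            Wave(
                adjacency=adjacency[m],
                behavior=codes[:, m].copy(),
                participating=~np.isnan(codes[:, m]),
                bmi_raw=None if raw is None else raw[:, m].copy(),
            )
        )
    panel = WavePanel(actor_ids, waves, wave_labels=[str(c) for c in wave_cols])

    covariates = None
    if covariates_file is not None:
        cov = pd.read_csv(covariates_file)
        cid = _find_column(cov.columns, _ID_NAMES, "actor id")
        covariates = CovariateTable(cov.set_index(cid)).reindex(actor_ids)
    return panel, covariates


def write_panel(panel: WavePanel, links_file, bmi_file, covariates: CovariateTable | None = None,
                covariates_file=None):
    """Write a panel in the formats :func:`read_panel` reads (codes, long links)."""
    rows = []
    for label, wave in zip(panel.wave_labels, panel.waves):
        egos, alters = np.nonzero(wave.adjacency)
        for e, a in zip(egos, alters):
            rows.append((panel.actor_ids[e], panel.actor_ids[a], label))
    pd.DataFrame(rows, columns=["ego_id", "alter_id", "wave"]).to_csv(links_file, index=False)

    bmi = pd.DataFrame({"id": panel.actor_ids})
    for label, wave in zip(panel.wave_labels, panel.waves):
        col = wave.behavior if wave.bmi_raw is None else wave.bmi_raw
        bmi[label] = col
    bmi.to_csv(bmi_file, index=False)

    if covariates is not None and covariates_file is not None:
        out = covariates.frame.copy()
        out.insert(0, "id", out.index)
        out.to_csv(covariates_file, index=False)


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def descriptives(panel: WavePanel) -> dict:
    """Per-wave network and behavior summaries plus first-to-last transitions.

    Out-degree statistics are taken over participating actors only; the
    increase/same/decrease split covers actors observed at both the first
    and the last wave and sums to 100%.
    """
    panel.validate()
    per_wave = []
    for label, wave in zip(panel.wave_labels, panel.waves):
        part = wave.participating
        outdeg = wave.adjacency.sum(axis=1)[part]
        codes = wave.behavior[part]
        entry = {
            "wave": label,
            "n_participating": int(part.sum()),
            "outdegree_mean": float(outdeg.mean()) if outdeg.size else float("nan"),
            "outdegree_sd": float(outdeg.std(ddof=1)) if outdeg.size > 1 else float("nan"),
            "category_mean": float(np.nanmean(codes)) if codes.size else float("nan"),
            "category_sd": float(np.nanstd(codes, ddof=1)) if codes.size > 1 else float("nan"),
            "category_counts": {
                CATEGORY_LABELS[c - 1]: int(np.nansum(codes == c)) for c in range(1, N_CATEGORIES + 1)
            },
        }
        if wave.bmi_raw is not None:
            raw = wave.bmi_raw[part]
            entry["bmi_mean"] = float(np.nanmean(raw))
            entry["bmi_sd"] = float(np.nanstd(raw, ddof=1))
        per_wave.append(entry)

    first, last = panel.waves[0].behavior, panel.waves[-1].behavior
    both = ~np.isnan(first) & ~np.isnan(last)
    n_both = int(both.sum())
    if n_both:
        diff = last[both] - first[both]
        split = {
            "increased_pct": 100.0 * float((diff > 0).mean()),
            "same_pct": 100.0 * float((diff == 0).mean()),
            "decreased_pct": 100.0 * float((diff < 0).mean()),
        }
    else:
        split = {"increased_pct": float("nan"), "same_pct": float("nan"),
                 "decreased_pct": float("nan")}
    return {
        "n_actors": panel.n_actors,
        "n_waves": panel.n_waves,
        "waves": per_wave,
        "category_change_first_to_last": {"n": n_both, **split},
    }


def write_descriptives(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
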