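"""Study bookkeeping statistics.

Small, exactly-defined quantities used around the imaging pipeline:

* pharmacokinetics — per-animal brain-to-plasma concentration ratios
  (brain ng/g divided by plasma ng/mL) and mean +/- SEM summaries per
  timepoint; a bundled reference table carries the measured cannabidiol
  concentrations at 1 h (Cmax) and 24 h (Cmin) after a 60 mg/kg oral dose,
  five rats per timepoint, with one 24 h brain sample excluded for
  inadequate perfusion;
* novel-object recognition — the discrimination index
  DI = (TN - TF) / (TN + TF) with the familiarization inclusion rule
  (at least 2.5 s of interaction with each object);
* pentylenetetrazole kindling — Racine-scale (0-5) bookkeeping: an animal
  is kindled at the second of the first two consecutive injections scoring
  4 or 5; animals with two consecutive stage-5 seizures on the first two
  doses are screened out; group summaries tabulate mortality, injections to
  kindling, per-injection generalized-seizure counts and latency/duration
  means.

Summaries report the mean of per-animal ratios (not the ratio of means);
SEM is the n-1 sample SD divided by sqrt(n).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

GENERALIZED_SCORE = 4  # Racine stage at/above which a seizure is generalized

# Measured cannabidiol concentrations (bundled reference dataset):
# plasma in ng/mL, brain in ng/g; empty brain cell = excluded sample.
_REFERENCE_PK_CSV = """\
rat,timepoint_h,plasma_ng_ml,brain_ng_g
1,1,259.93,1058.50
2,1,6326.57,16886.61
3,1,800.39,1475.58
4,1,198.69,642.07
5,1,2295.02,2455.34
6,24,23.20,111.08
7,24,26.20,79.98
8,24,28.67,105.28
9,24,22.50,
10,24,20.40,69.35
"""


def load_reference_pk() -> pd.DataFrame:
    """The bundled plasma/brain concentration table (one row per rat)."""
    return pd.read_csv(io.StringIO(_REFERENCE_PK_CSV))


# ---------------------------------------------------------------------------
# pharmacokinetics
# ---------------------------------------------------------------------------


def brain_plasma_ratio(plasma_ng_ml: float, brain_ng_g: float | None,
                       decimals: int | None = 3) -> float:
    """Brain-to-plasma ratio for one animal; NaN when the brain sample is absent."""
    if plasma_ng_ml is None or plasma_ng_ml <= 0:
        raise ValueError("plasma concentration must be positive")
    if brain_ng_g is None or (isinstance(brain_ng_g, float) and np.isnan(brain_ng_g)):
        return float("nan")
    if brain_ng_g <= 0:
        raise ValueError("brain concentration must be positive when present")
    ratio = brain_ng_g / plasma_ng_ml
    return round(ratio, decimals) if decimals is not None else ratio


def add_ratios(pk: pd.DataFrame, decimals: int | None = 3) -> pd.DataFrame:
    """Append a ``ratio`` column (NaN where the brain sample is missing)."""
    out = pk.copy()
    out["ratio"] = [
        brain_plasma_ratio(p, b, decimals=decimals)
        for p, b in zip(out["plasma_ng_ml"], out["brain_ng_g"])
    ]
    return out


def mean_sem(values, as_sd: bool = False) -> tuple[float, float]:
    """Arithmetic mean and SEM (= sample SD / sqrt(n), ddof = 1).

    ``as_sd`` returns the sample SD in place of the SEM, a compatibility
    convention occasionally seen in printed tables.
    """
    vals = np.asarray([v for v in np.atleast_1d(values) if np.isfinite(v)],
                      dtype=float)
    n = vals.size
    if n < 2:
        raise ValueError("mean_sem needs at least two values")
    sd = float(vals.std(ddof=1))
    return float(vals.mean()), sd if as_sd else sd / float(np.sqrt(n))


def pk_summary(pk: pd.DataFrame | None = None, decimals: int | None = None) -> pd.DataFrame:
    """Per-timepoint plasma/brain/ratio means and SEMs (mean of per-rat ratios).

    Ratios enter the summary at full precision; rounding (``decimals``) is a
    display choice only.
    """
    pk = add_ratios(load_reference_pk() if pk is None else pk, decimals=decimals)
    rows = []
    for tp, grp in pk.groupby("timepoint_h"):
        row: dict = {"timepoint_h": tp, "n": len(grp)}
        for col, name in (("plasma_ng_ml", "plasma"), ("brain_ng_g", "brain"),
                          ("ratio", "ratio")):
            vals = grp[col].dropna()
            row[f"{name}_n"] = len(vals)
            row[f"{name}_mean"], row[f"{name}_sem"] = mean_sem(vals)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# novel object recognition
# ---------------------------------------------------------------------------

MIN_FAMILIARIZATION_S = 2.5


def discrimination_index(tn_s: float, tf_s: float,
                         fam1_s: float | None = None,
                         fam2_s: float | None = None) -> float:
    """DI = (TN - TF) / (TN + TF), in [-1, 1].

    TN/TF are the exploration times of the novel and familiar object.  When
    familiarization interaction times are supplied the inclusion rule is
    enforced: at least 2.5 s with each object, else the trial is invalid.
    """
    if tn_s < 0 or tf_s < 0:
        raise ValueError("exploration times must be non-negative")
    for fam in (fam1_s, fam2_s):
        if fam is not None and fam < MIN_FAMILIARIZATION_S:
            raise ValueError(
                f"familiarization below {MIN_FAMILIARIZATION_S} s: trial excluded"
            )
    total = tn_s + tf_s
    if total == 0:
        raise ValueError("zero total exploration time: DI undefined")
    return (tn_s - tf_s) / total


# ---------------------------------------------------------------------------
# kindling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeizureLog:
    """One animal's per-injection record.

    ``scores`` are modified Racine stages, integers 0-5 (0 no response,
    1 ear/facial twitching, 2 myoclonic jerks, 3 jerks with rearing,
    4 tonic-clonic in side position, 5 generalized tonic-clonic with loss
    of balance).  ``latency_s``/``duration_s`` align with ``scores`` and are
    present (finite) exactly for generalized (>= stage 4) seizures.
    """

    scores: tuple[int, ...]
    latency_s: tuple[float, ...] = ()
    duration_s: tuple[float, ...] = ()
    survived: bool = True

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValueError("empty seizure log")
        if any((not float(s).is_integer()) or not (0 <= s <= 5) for s in self.scores):
            raise ValueError("Racine scores must be integers in 0..5")
        for arr in (self.latency_s, self.duration_s):
            if arr and len(arr) != len(self.scores):
                raise ValueError("latency/duration must align with scores")


def kindled_at(log: SeizureLog | tuple[int, ...] | list[int]) -> int | None:
    """1-based injection index at which the animal became kindled.

    Kindled = stage >= 4 on two consecutive injections; returns the index of
    the second of the first such pair, or None if never kindled.
    """
    scores = log.scores if isinstance(log, SeizureLog) else tuple(log)
    if not scores:
        raise ValueError("empty seizure log")
    for i in range(1, len(scores)):
        if scores[i - 1] >= GENERALIZED_SCORE and scores[i] >= GENERALIZED_SCORE:
            return i + 1
    return None


def sensitivity_excluded(log: SeizureLog | tuple[int, ...] | list[int]) -> bool:
    """Entry screen: two consecutive stage-5 seizures on the first two doses."""
    scores = log.scores if isinstance(log, SeizureLog) else tuple(log)
    return len(scores) >= 2 and scores[0] == 5 and scores[1] == 5


def seizure_summary(groups: dict[str, list[SeizureLog]]) -> pd.DataFrame:
    """Descriptive kindling summary per treatment group.

    Tabulates mortality fraction, injections-to-kindled (mean/median over
    kindled animals), total generalized-seizure counts per injection rank,
    and latency/duration of generalized seizures as mean +/- SEM.
    Inferential testing is delegated to standard statistical routines.
    """
    rows = []
    for name, logs in groups.items():
        if not logs:
            raise ValueError(f"group {name!r} is empty")
        n = len(logs)
        deaths = sum(0 if lg.survived else 1 for lg in logs)
        kindle_idx = [kindled_at(lg) for lg in logs]
        kindled = [k for k in kindle_idx if k is not None]
        lat = [v for lg in logs for s, v in zip(lg.scores, lg.latency_s)
               if s >= GENERALIZED_SCORE and np.isfinite(v)]
        dur = [v for lg in logs for s, v in zip(lg.scores, lg.duration_s)
               if s >= GENERALIZED_SCORE and np.isfinite(v)]
        max_len = max(len(lg.scores) for lg in logs)
        per_injection = [
            sum(1 for lg in logs
                if len(lg.scores) > j and lg.scores[j] >= GENERALIZED_SCORE)
            for j in range(max_len)
        ]
        row = {
            "group": name,
            "n": n,
            "n_died": deaths,
            "mortality": deaths / n,
            "n_kindled": len(kindled),
            "injections_to_kindled_mean": float(np.mean(kindled)) if kindled else np.nan,
            "injections_to_kindled_median": float(np.median(kindled)) if kindled else np.nan,
            "generalized_per_injection": per_injection,
        }
        for label, vals in (("latency_s", lat), ("duration_s", dur)):
            if len(vals) >= 2:
                row[f"{label}_mean"], row[f"{label}_sem"] = mean_sem(vals)
            elif len(vals) == 1:
                row[f"{label}_mean"], row[f"{label}_sem"] = float(vals[0]), np.nan
            else:
                row[f"{label}_mean"] = row[f"{label}_sem"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def logs_from_table(df: pd.DataFrame) -> dict[str, list[SeizureLog]]:
    """Build per-group :class:`SeizureLog` lists from a long-format table.

    Expected columns: rat, group, injection, score, latency_s, duration_s,
    survived (per-rat flag, constant across its rows).
    """
    groups: dict[str, list[SeizureLog]] = {}
    for (grp, _rat), sub in df.sort_values("injection").groupby(["group", "rat"]):
        n = len(sub)
        lat = tuple(float(v) for v in sub["latency_s"]) if "latency_s" in sub else (np.nan,) * n
        dur = tuple(float(v) for v in sub["duration_s"]) if "duration_s" in sub else (np.nan,) * n
        log = SeizureLog(
            scores=tuple(int(s) for s in sub["score"]),
            latency_s=lat,
            duration_s=dur,
            survived=bool(sub["survived"].iloc[0]) if "survived" in sub else True,
        )
        groups.setdefault(str(grp), []).append(log)
    return groups
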