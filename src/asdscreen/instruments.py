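"""Scoring and DSM-5 classification of the ASDS and PCL-5 questionnaires.

The Acute Stress Disorder Scale (ASDS) carries 19 symptom items rated 1-5
(1 = not at all, 5 = very much) plus a binary peritraumatic-fear item; the
item sum is the acute-stress *intensity* score (range 19-95).  Probable
DSM-5 acute stress disorder (ASD) is defined as endorsing at least 9 of the
14 DSM-5-relevant symptoms; because several symptoms are probed by more than
one item, an explicit item-to-symptom map (:class:`SymptomMap`) turns item
responses into symptom endorsements.

The PCL-5 carries 20 items rated 0-4, one per DSM-5 PTSD symptom, grouped
into criteria B (intrusion, items 1-5), C (avoidance, 6-7), D (negative
cognitions/mood, 8-14) and E (arousal/reactivity, 15-20).  Full-threshold
caseness requires >=1 B, >=1 C, >=2 D and >=2 E endorsed items; the two
subthreshold definitions are 'Majority' (full threshold on at least 3 of the
4 criteria) and 'Six Plus' (at least 6 endorsed symptoms anywhere).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ASDS_MIN_TOTAL",
    "ASDS_MAX_TOTAL",
    "DEFAULT_ASDS_CUTOFF",
    "DEFAULT_SYMPTOM_MAP",
    "DEFAULT_PCL5_PARTITION",
    "AsdsResponse",
    "AsdsResult",
    "Pcl5Response",
    "Pcl5Result",
    "SubjectRecord",
    "SymptomMap",
    "ValidationError",
    "classify_wave",
    "diagnose_ptsd",
    "load_config",
    "read_cohort_csv",
    "score_asds",
    "write_cohort_csv",
]

ASDS_N_ITEMS = 19
ASDS_MIN_TOTAL = 19
ASDS_MAX_TOTAL = 95
ASDS_N_SYMPTOMS = 14
PCL5_N_ITEMS = 20
DEFAULT_ASDS_CUTOFF = 58

#: DSM-5 PTSD criterion partition of the PCL-5 items (1-based, DSM item order)
DEFAULT_PCL5_PARTITION: dict[str, tuple[int, ...]] = {
    "B": tuple(range(1, 6)),
    "C": (6, 7),
    "D": tuple(range(8, 15)),
    "E": tuple(range(15, 21)),
}

#: Minimum endorsed-item counts per criterion for full-threshold DSM-5 PTSD
PCL5_CRITERION_MINIMA: dict[str, int] = {"B": 1, "C": 1, "D": 2, "E": 2}


class ValidationError(ValueError):
    """An item vector or record violates an instrument invariant."""


@dataclass(frozen=True)
class AsdsResponse:
    """One subject's ASDS form at one acute wave.

    ``items`` are the 19 symptom ratings in instrument order, each in 1..5;
    ``fear`` is the binary peritraumatic-fear item (item 20); ``wave`` is
    ``"W1"`` (9-15 days post trauma) or ``"W2"`` (21-27 days).
    """

    items: tuple[int, ...]
    fear: bool = False
    wave: str = "W1"

    def __post_init__(self) -> None:
        if len(self.items) != ASDS_N_ITEMS:
            raise ValidationError(
                f"ASDS requires exactly {ASDS_N_ITEMS} items, got {len(self.items)}"
            )
        for i, v in enumerate(self.items, start=1):
            if not (isinstance(v, (int,)) and 1 <= v <= 5):
                raise ValidationError(
                    f"ASDS item {i} must be an integer in [1, 5], got {v!r}"
                )
        if self.wave not in ("W1", "W2"):
            raise ValidationError(f"wave must be 'W1' or 'W2', got {self.wave!r}")


@dataclass(frozen=True)
class SymptomMap:
    """Assignment of ASDS items to the 14 DSM-5 ASD symptoms.

    ``entries`` maps each symptom id (1..14) to the non-empty set of item
    indices (1..19) probing it; a symptom fed by several items is endorsed by
    the maximum of its items.  ``endorsement_threshold`` is the minimum item
    rating (on the 1-5 scale) counting as symptom endorsement; the default 3
    is the scale midpoint.
    """

    entries: Mapping[int, frozenset[int]]
    endorsement_threshold: int = 3

    def __post_init__(self) -> None:
        ids = sorted(self.entries)
        if ids != list(range(1, ASDS_N_SYMPTOMS + 1)):
            raise ValidationError(
                f"symptom map must cover symptom ids 1..{ASDS_N_SYMPTOMS} exactly once"
            )
        for sid, items in self.entries.items():
            if not items:
                raise ValidationError(f"symptom {sid} has no items")
            for idx in items:
                if not 1 <= idx <= ASDS_N_ITEMS:
                    raise ValidationError(
                        f"symptom {sid} references invalid item index {idx}"
                    )
        if not 2 <= self.endorsement_threshold <= 5:
            raise ValidationError(
                "endorsement_threshold must lie in [2, 5] "
                f"(got {self.endorsement_threshold})"
            )

    def endorsed_symptoms(self, items: Sequence[int]) -> list[bool]:
        """Per-symptom endorsement flags (index 0 = symptom 1)."""
        return [
            max(items[i - 1] for i in self.entries[sid]) >= self.endorsement_threshold
            for sid in range(1, ASDS_N_SYMPTOMS + 1)
        ]


def _default_symptom_entries() -> dict[int, frozenset[int]]:
    # Symptoms 1-9 <- items 1-9 one-to-one; symptoms 10-14 <- consecutive
    # item pairs (10,11) .. (18,19). The published instrument's mapping is
    # not reproduced here; substitute it via a config file when available.
    entries = {s: frozenset({s}) for s in range(1, 10)}
    for k, first in enumerate(range(10, ASDS_N_ITEMS, 2), start=10):
        entries[k] = frozenset({first, first + 1})
    return entries


#: Default item->symptom assignment (documented placeholder: the scale's
#: published mapping is configurable, the 9-of-14 rule itself is fixed).
DEFAULT_SYMPTOM_MAP = SymptomMap(entries=_default_symptom_entries())


@dataclass(frozen=True)
class AsdsResult:
    """Scored ASDS: intensity total, symptom count and diagnostic flags."""

    total: int
    symptom_count: int
    asd_diagnosis: bool
    intensity_class: str  # "low" | "high"
    cutoff_used: int
    wave: str
    fear: bool


def score_asds(
    response: AsdsResponse,
    symptom_map: SymptomMap = DEFAULT_SYMPTOM_MAP,
    cutoff: int = DEFAULT_ASDS_CUTOFF,
    strict_cutoff: bool = False,
) -> AsdsResult:
    """Score one ASDS response.

    Parameters
    ----------
    response : AsdsResponse
        Validated 19-item response.
    symptom_map : SymptomMap
        Item-to-symptom assignment and endorsement level.
    cutoff : int
        Intensity cut-off on the 19-95 total; the default 58 is the
        Youden-selected screening threshold.
    strict_cutoff : bool
        If True, high intensity requires ``total > cutoff``; by default the
        conventional ``total >= cutoff``.

    Returns
    -------
    AsdsResult
        ``total`` is the item sum; ``asd_diagnosis`` is True iff at least 9
        of the 14 DSM-5 symptoms are endorsed.
    """
    if not ASDS_MIN_TOTAL <= cutoff <= ASDS_MAX_TOTAL:
        raise ValidationError(
            f"cutoff must lie in [{ASDS_MIN_TOTAL}, {ASDS_MAX_TOTAL}], got {cutoff}"
        )
    total = int(sum(response.items))
    symptom_count = int(sum(symptom_map.endorsed_symptoms(response.items)))
    high = total > cutoff if strict_cutoff else total >= cutoff
    return AsdsResult(
        total=total,
        symptom_count=symptom_count,
        asd_diagnosis=symptom_count >= 9,
        intensity_class="high" if high else "low",
        cutoff_used=int(cutoff),
        wave=response.wave,
        fear=response.fear,
    )


@dataclass(frozen=True)
class Pcl5Response:
    """One subject's PCL-5 form (20 items, each 0..4)."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != PCL5_N_ITEMS:
            raise ValidationError(
                f"PCL-5 requires exactly {PCL5_N_ITEMS} items, got {len(self.items)}"
            )
        for i, v in enumerate(self.items, start=1):
            if not (isinstance(v, (int,)) and 0 <= v <= 4):
                raise ValidationError(
                    f"PCL-5 item {i} must be an integer in [0, 4], got {v!r}"
                )


@dataclass(frozen=True)
class Pcl5Result:
    """Scored PCL-5 with full-threshold and subthreshold caseness flags."""

    severity: int
    endorsed: tuple[bool, ...]
    criterion_counts: tuple[int, int, int, int]  # (B, C, D, E)
    full_threshold: bool
    majority: bool
    six_plus: bool

    @property
    def any_case(self) -> bool:
        """Full-threshold or either subthreshold definition."""
        return self.full_threshold or self.majority or self.six_plus


def diagnose_ptsd(
    response: Pcl5Response,
    endorsement_threshold: int = 2,
    partition: Mapping[str, Sequence[int]] = DEFAULT_PCL5_PARTITION,
) -> Pcl5Result:
    """Apply the DSM-5 PTSD rule and both subthreshold definitions.

    An item counts as an endorsed symptom when rated at least
    ``endorsement_threshold`` (default 2, "moderately" — the standard PCL-5
    convention).  Full threshold requires endorsed counts >= (1, 1, 2, 2)
    over criteria (B, C, D, E); 'Majority' requires at least 3 of those 4
    componentwise conditions; 'Six Plus' requires >= 6 endorsed symptoms
    regardless of criterion.
    """
    if not 1 <= endorsement_threshold <= 4:
        raise ValidationError(
            f"endorsement_threshold must lie in [1, 4], got {endorsement_threshold}"
        )
    covered = sorted(i for items in partition.values() for i in items)
    if covered != list(range(1, PCL5_N_ITEMS + 1)) or set(partition) != {
        "B",
        "C",
        "D",
        "E",
    }:
        raise ValidationError("criterion partition must cover items 1..20 exactly once")
    endorsed = tuple(v >= endorsement_threshold for v in response.items)
    counts = tuple(
        sum(endorsed[i - 1] for i in partition[c]) for c in ("B", "C", "D", "E")
    )
    met = [
        counts[k] >= PCL5_CRITERION_MINIMA[c] for k, c in enumerate(("B", "C", "D", "E"))
    ]
    return Pcl5Result(
        severity=int(sum(response.items)),
        endorsed=endorsed,
        criterion_counts=counts,  # type: ignore[arg-type]
        full_threshold=all(met),
        majority=sum(met) >= 3,
        six_plus=sum(endorsed) >= 6,
    )


@dataclass
class SubjectRecord:
    """One participant: wave-wise responses, demographics, participation mask."""

    subject_id: str
    age: float | None = None
    gender: str | None = None
    profession: str | None = None
    asds_w1: AsdsResponse | None = None
    asds_w2: AsdsResponse | None = None
    pcl5: Pcl5Response | None = None

    @property
    def participation(self) -> tuple[bool, bool, bool]:
        """(has W1 ASDS, has W2 ASDS, has W3 PCL-5)."""
        return (self.asds_w1 is not None, self.asds_w2 is not None, self.pcl5 is not None)

    @property
    def complete(self) -> bool:
        """At least one acute wave plus the follow-up outcome."""
        w1, w2, w3 = self.participation
        return (w1 or w2) and w3


@dataclass
class WaveTables:
    """Per-wave scored flag tables plus the exclusion log."""

    w1: pd.DataFrame
    w2: pd.DataFrame
    exclusions: pd.DataFrame

    def table(self, wave: str) -> pd.DataFrame:
        return {"W1": self.w1, "W2": self.w2}[wave]


def classify_wave(
    records: Iterable[SubjectRecord],
    symptom_map: SymptomMap = DEFAULT_SYMPTOM_MAP,
    cutoff: int = DEFAULT_ASDS_CUTOFF,
    pcl5_threshold: int = 2,
    strict_cutoff: bool = False,
) -> WaveTables:
    """Score a cohort and build per-wave ASD/PTSD flag tables.

    Each wave table holds one row per subject with a valid ASDS at that wave
    *and* a valid PCL-5 at follow-up: intensity total, diagnosis and
    intensity flags, plus the four PTSD outcome flags.  Subjects lacking the
    follow-up (or any acute wave) are excluded from the corresponding tables
    and listed, with reasons, in the exclusion log.
    """
    rows: dict[str, list[dict]] = {"W1": [], "W2": []}
    excl: list[dict] = []
    for rec in records:
        if rec.pcl5 is None:
            excl.append({"subject_id": rec.subject_id, "reason": "missing wave-3 PCL-5"})
            continue
        if rec.asds_w1 is None and rec.asds_w2 is None:
            excl.append({"subject_id": rec.subject_id, "reason": "no acute-wave ASDS"})
            continue
        ptsd = diagnose_ptsd(rec.pcl5, endorsement_threshold=pcl5_threshold)
        for wave, resp in (("W1", rec.asds_w1), ("W2", rec.asds_w2)):
            if resp is None:
                continue
            asd = score_asds(resp, symptom_map, cutoff, strict_cutoff)
            rows[wave].append(
                {
                    "subject_id": rec.subject_id,
                    "wave": wave,
                    "asds_total": asd.total,
                    "symptom_count": asd.symptom_count,
                    "asd_diagnosis": asd.asd_diagnosis,
                    "intensity_class": asd.intensity_class,
                    "ptsd_full": ptsd.full_threshold,
                    "ptsd_majority": ptsd.majority,
                    "ptsd_six_plus": ptsd.six_plus,
                    "ptsd_any": ptsd.any_case,
                    "pcl5_severity": ptsd.severity,
                }
            )
    cols = [
        "subject_id",
        "wave",
        "asds_total",
        "symptom_count",
        "asd_diagnosis",
        "intensity_class",
        "ptsd_full",
        "ptsd_majority",
        "ptsd_six_plus",
        "ptsd_any",
        "pcl5_severity",
    ]
    return WaveTables(
        w1=pd.DataFrame(rows["W1"], columns=cols),
        w2=pd.DataFrame(rows["W2"], columns=cols),
        exclusions=pd.DataFrame(excl, columns=["subject_id", "reason"]),
    )


# ---------------------------------------------------------------------------
# CSV schema: one row per subject per wave per instrument
# ---------------------------------------------------------------------------

_ITEM_COLS = [f"item_{i:02d}" for i in range(1, 21)]
CSV_COLUMNS = ["subject_id", "wave", "instrument"] + _ITEM_COLS + [
    "age",
    "gender",
    "profession",
]


def _prorate_total(values: list[int | None]) -> int | None:
    """Prorated ASDS total when >=80% of items are answered.

    prorate = mean of answered x 19, rounded half-up. Used only for the
    intensity total, never for symptom counting.
    """
    answered = [v for v in values if v is not None]
    if len(answered) < 0.8 * ASDS_N_ITEMS:
        return None
    from decimal import ROUND_HALF_UP, Decimal

    mean = Decimal(sum(answered)) / Decimal(len(answered))
    return int((mean * ASDS_N_ITEMS).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def read_cohort_csv(path: str | Path) -> list[SubjectRecord]:
    """Read the long-format cohort CSV into :class:`SubjectRecord` objects.

    Expected columns: ``subject_id, wave (1|2|3), instrument (ASDS|PCL5),
    item_01..item_20, age, gender, profession``.  For ASDS rows item_20 is
    the binary fear flag; for PCL5 rows all 20 items are symptom ratings.
    Malformed rows raise :class:`ValidationError` naming the row number.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort CSV is missing columns: {missing}")
    records: dict[str, SubjectRecord] = {}
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        sid = str(row.subject_id)
        rec = records.setdefault(sid, SubjectRecord(subject_id=sid))
        for attr in ("age", "gender", "profession"):
            val = getattr(row, attr)
            if pd.notna(val) and getattr(rec, attr) is None:
                setattr(rec, attr, float(val) if attr == "age" else str(val))
        try:
            wave = int(row.wave)
            instrument = str(row.instrument).upper()
            raw = [getattr(row, c) for c in _ITEM_COLS]
            if instrument == "ASDS":
                if wave not in (1, 2):
                    raise ValidationError(f"ASDS rows must have wave 1 or 2, got {wave}")
                items = tuple(int(v) for v in raw[:ASDS_N_ITEMS])
                fear = bool(int(raw[19])) if pd.notna(raw[19]) else False
                resp = AsdsResponse(items=items, fear=fear, wave=f"W{wave}")
                setattr(rec, f"asds_w{wave}", resp)
            elif instrument == "PCL5":
                if wave != 3:
                    raise ValidationError(f"PCL5 rows must have wave 3, got {wave}")
                rec.pcl5 = Pcl5Response(items=tuple(int(v) for v in raw))
            else:
                raise ValidationError(f"unknown instrument {instrument!r}")
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"line {pos}: {exc}") from exc
    return list(records.values())


def write_cohort_csv(records: Iterable[SubjectRecord], path: str | Path) -> None:
    """Write records back to the long-format CSV schema (inverse of read)."""
    rows = []
    for rec in records:
        base = {"subject_id": rec.subject_id, "age": rec.age, "gender": rec.gender,
                "profession": rec.profession}
        for wave, resp in ((1, rec.asds_w1), (2, rec.asds_w2)):
            if resp is None:
                continue
            row = dict(base, wave=wave, instrument="ASDS")
            for i, v in enumerate(resp.items, start=1):
                row[f"item_{i:02d}"] = v
            row["item_20"] = int(resp.fear)
            rows.append(row)
        if rec.pcl5 is not None:
            row = dict(base, wave=3, instrument="PCL5")
            for i, v in enumerate(rec.pcl5.items, start=1):
                row[f"item_{i:02d}"] = v
            rows.append(row)
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load thresholds and an optional symptom map from a key=value file.

    Recognised keys: ``asds_endorsement_threshold``, ``pcl5_endorsement_threshold``,
    ``asds_cutoff``, ``strict_cutoff`` and ``symptom_<k> = i[,j,...]`` lines
    (all 14 required if any is given).  Lines starting with ``#`` are comments.
    """
    values: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(f"config line {lineno}: expected key = value")
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip()

    out: dict = {
        "asds_cutoff": int(values.pop("asds_cutoff", DEFAULT_ASDS_CUTOFF)),
        "pcl5_endorsement_threshold": int(values.pop("pcl5_endorsement_threshold", 2)),
        "strict_cutoff": values.pop("strict_cutoff", "false").lower() in ("1", "true"),
    }
    asds_thr = int(
        values.pop("asds_endorsement_threshold", DEFAULT_SYMPTOM_MAP.endorsement_threshold)
    )
    map_lines = {k: v for k, v in values.items() if k.startswith("symptom_")}
    if map_lines:
        entries = {
            int(k.split("_", 1)[1]): frozenset(int(x) for x in v.split(","))
            for k, v in map_lines.items()
        }
        out["symptom_map"] = SymptomMap(entries=entries, endorsement_threshold=asds_thr)
    else:
        out["symptom_map"] = SymptomMap(
            entries=_default_symptom_entries(), endorsement_threshold=asds_thr
        )
    unknown = set(values) - set(map_lines)
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return out
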