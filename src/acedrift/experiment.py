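"""Canonical schema and IO for transmission-chain experiment data.

The experiment transmits a handaxe image along chains of participants on a
touch screen: each participant resizes a fresh image to match the previous
participant's image.  One record is one transmission event:

    condition        "larger" or "smaller" (initial size of the image the
                     participant resizes relative to the target)
    chain_id         chain identifier within the condition
    generation       1..T (generation 0 is the fixed 10 cm seed image)
    target_size_cm   height of the image being copied (left image)
    produced_size_cm height the participant produced (right image)

Sizes are stored as heights in cm; image width is always 7/15 of height
and is never stored.  The canonical file format is a plain UTF-8 CSV with
exactly those columns; a column-mapping dict adapts externally produced
files with different headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataSchemaError, RecordValidationError

__all__ = [
    "CONDITIONS",
    "SCREEN_MAX_CM",
    "SEED_SIZE_CM",
    "TransmissionRecord",
    "CopyingErrorSample",
    "read_experiment_csv",
    "write_experiment_csv",
    "records_to_frame",
    "frame_to_records",
    "validate_records",
    "compute_copying_errors",
]

logger = logging.getLogger(__name__)

CONDITIONS = ("larger", "smaller")
#: physical screen height: no produced image can exceed it
SCREEN_MAX_CM = 14.4
#: height of the generation-0 target image in every chain
SEED_SIZE_CM = 10.0

_COLUMNS = ["condition", "chain_id", "generation", "target_size_cm", "produced_size_cm"]


@dataclass(frozen=True)
class TransmissionRecord:
    """A single copying event within one chain."""

    condition: str
    chain_id: str
    generation: int
    target_size_cm: float
    produced_size_cm: float


@dataclass(frozen=True)
class CopyingErrorSample:
    """Observed copying-error ratios (produced/target), one per event."""

    ratios: np.ndarray = field(repr=False)
    conditions: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.ratios.size

    def for_condition(self, condition: str) -> np.ndarray:
        return self.ratios[self.conditions == condition]


def records_to_frame(records: list[TransmissionRecord]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [(r.condition, r.chain_id, r.generation, r.target_size_cm, r.produced_size_cm)
         for r in records],
        columns=_COLUMNS,
    )
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[TransmissionRecord]:
    return [
        TransmissionRecord(
            condition=str(row.condition),
            chain_id=str(row.chain_id),
            generation=int(row.generation),
            target_size_cm=float(row.target_size_cm),
            produced_size_cm=float(row.produced_size_cm),
        )
        for row in frame.itertuples(index=False)
    ]


def read_experiment_csv(path: str | Path,
                        column_map: dict[str, str] | None = None,
                        validate: bool = True,
                        x0: float | None = SEED_SIZE_CM) -> list[TransmissionRecord]:
    """Read transmission records from a CSV file.

    Parameters
    ----------
    path:
        CSV file with a header row.
    column_map:
        Optional mapping from source column names to canonical names, for
        externally produced files whose layout differs from the canonical
        schema.
    validate:
        If True, run :func:`validate_records` in warning mode (external
        files may carry rounding that breaks exact chain linkage, so
        ingestion never hard-fails on consistency).
    x0:
        Expected generation-1 target size; pass ``None`` to skip that check.
    """
    path = Path(path)
    if not path.exists():
        raise DataSchemaError(f"no such file: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        frame = frame.rename(columns=column_map)
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise DataSchemaError(
            f"{path}: missing required column(s) {missing}; found {list(frame.columns)}"
        )
    extra = [c for c in frame.columns if c not in _COLUMNS]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)
        frame = frame[_COLUMNS]

    for col in ("generation", "target_size_cm", "produced_size_cm"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0]) + 2  # 1-based + header
            raise DataSchemaError(
                f"{path}: non-numeric value in column {col!r} at line {row}")
        frame[col] = coerced

    frame = frame.sort_values(["condition", "chain_id", "generation"],
                              kind="stable").reset_index(drop=True)
    records = frame_to_records(frame)
    if validate:
        validate_records(records, x0=x0, on_error="warn")
    return records


def write_experiment_csv(records: list[TransmissionRecord], path: str | Path,
                         x0: float | None = SEED_SIZE_CM) -> None:
    """Write records to the canonical CSV after validating their invariants.

    Validation runs in strict mode before anything touches the disk: a
    record set with broken chain linkage or out-of-bounds sizes is refused.
    """
    validate_records(records, x0=x0, on_error="raise")
    records_to_frame(records).to_csv(path, index=False)


def validate_records(records: list[TransmissionRecord],
                     x0: float | None = SEED_SIZE_CM,
                     screen_max: float = SCREEN_MAX_CM,
                     link_rtol: float = 1e-6,
                     on_error: str = "raise") -> list[str]:
    """Check structural invariants of a transmission-record set.

    Checks: condition labels; positive sizes bounded by the screen height;
    generation-1 targets equal to the seed size ``x0``; within-chain
    linkage (the target at generation g equals the produced size at g-1,
    to relative tolerance ``link_rtol``, absorbing rounding in external
    files).

    Returns the list of issue descriptions; raises
    :class:`RecordValidationError` on the first report when
    ``on_error="raise"``, or logs warnings when ``on_error="warn"``.
    """
    issues: list[str] = []
    for r in records:
        if r.condition not in CONDITIONS:
            issues.append(f"unknown condition {r.condition!r} (chain {r.chain_id})")
        if not (0 < r.produced_size_cm <= screen_max):
            issues.append(
                f"produced size {r.produced_size_cm} cm outside (0, {screen_max}] "
                f"(chain {r.chain_id}, generation {r.generation})")
        if r.target_size_cm <= 0:
            issues.append(
                f"non-positive target size {r.target_size_cm} cm "
                f"(chain {r.chain_id}, generation {r.generation})")
        if r.generation < 1:
            issues.append(f"generation {r.generation} < 1 (chain {r.chain_id})")

    by_chain: dict[tuple[str, str], list[TransmissionRecord]] = {}
    for r in records:
        by_chain.setdefault((r.condition, r.chain_id), []).append(r)
    for (cond, chain), chain_records in by_chain.items():
        chain_records = sorted(chain_records, key=lambda r: r.generation)
        gens = [r.generation for r in chain_records]
        if gens != list(range(1, len(gens) + 1)):
            issues.append(f"chain {cond}/{chain}: generations {gens} are not 1..{len(gens)}")
            continue
        first = chain_records[0]
        if x0 is not None and not np.isclose(first.target_size_cm, x0, rtol=link_rtol):
            issues.append(
                f"chain {cond}/{chain}: generation-1 target "
                f"{first.target_size_cm} != seed size {x0}")
        for prev, cur in zip(chain_records, chain_records[1:]):
            if not np.isclose(cur.target_size_cm, prev.produced_size_cm, rtol=link_rtol):
                issues.append(
                    f"chain {cond}/{chain}: target at generation {cur.generation} "
                    f"({cur.target_size_cm}) != produced at generation "
                    f"{prev.generation} ({prev.produced_size_cm})")

    if issues:
        if on_error == "raise":
            raise RecordValidationError("; ".join(issues))
        for issue in issues:
            logger.warning("record validation: %s", issue)
    return issues


def compute_copying_errors(records: list[TransmissionRecord]) -> CopyingErrorSample:
    """Copying-error ratio (produced/target) for every transmission event.

    The ratio realizes the model's error variable eps for that event; its
    sample sd across events estimates the copying-error parameter sigma.
    """
    for r in records:
        if r.target_size_cm <= 0:
            raise RecordValidationError(
                f"target size must be positive to form a ratio "
                f"(chain {r.chain_id}, generation {r.generation})")
    ratios = np.array([r.produced_size_cm / r.target_size_cm for r in records])
    conditions = np.array([r.condition for r in records])
    return CopyingErrorSample(ratios=ratios, conditions=conditions)
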