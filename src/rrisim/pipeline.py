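"""Orchestration: beat data -> epoch selection -> similarity scores table."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .ingest import (IngestError, QualityConfig, beats_to_rri, read_beats,
                     select_epochs)
from .similarity import SimilarityConfig, SimilarityError, score_epoch

log = logging.getLogger(__name__)

SCORE_COLUMNS = ["mother_id", "fetus_id", "epoch_index", "ed", "group",
                 "cc1", "cc2", "clf", "chf", "n_valid_windows", "excluded"]


def score_dyad(maternal_beats, fetal_beats, config=None, quality=None,
               n_epochs: int = 2, epoch_len_ms: float = 180_000.0):
    """Select clean epochs for one dyad and score each.

    Returns ``(scores, complete)`` where ``scores`` is a list of
    (epoch_index, SimilarityScores) and ``complete`` is False when fewer
    than ``n_epochs`` clean epochs were found.
    """
    m_tach = beats_to_rri(maternal_beats)
    f_tach = beats_to_rri(fetal_beats)
    epochs, complete = select_epochs(m_tach, f_tach, epoch_len_ms=epoch_len_ms,
                                     n_epochs=n_epochs, quality=quality)
    return [(i, score_epoch(ep, config)) for i, ep in enumerate(epochs)], complete


def analyze_records(records, config: SimilarityConfig | None = None,
                    quality: QualityConfig | None = None,
                    n_epochs: int = 2) -> pd.DataFrame:
    """Score a list of in-memory dyad records (see simulate.DyadRecord).

    Dyads without the required number of clean epochs are flagged
    ``excluded`` but their available epochs are still reported.
    """
    rows = []
    for rec in records:
        try:
            scored, complete = score_dyad(rec.maternal, rec.fetal, config,
                                          quality, n_epochs=n_epochs)
        except (IngestError, SimilarityError) as e:
            log.warning("dyad %s/%s failed: %s", rec.mother_id, rec.fetus_id, e)
            rows.append({"mother_id": rec.mother_id, "fetus_id": rec.fetus_id,
                         "epoch_index": -1, "ed": rec.ed, "group": rec.group,
                         "cc1": float("nan"), "cc2": float("nan"),
                         "clf": float("nan"), "chf": float("nan"),
                         "n_valid_windows": 0, "excluded": True})
            continue
        for i, s in scored:
            rows.append({"mother_id": rec.mother_id, "fetus_id": rec.fetus_id,
                         "epoch_index": i, "ed": rec.ed, "group": rec.group,
                         "cc1": s.cc1, "cc2": s.cc2, "clf": s.clf,
                         "chf": s.chf, "n_valid_windows": s.n_valid_windows,
                         "excluded": not complete})
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


class _FileDyad:
    def __init__(self, row, base: Path):
        self.mother_id = row["mother_id"]
        self.fetus_id = row["fetus_id"]
        self.ed = row.get("ed", float("nan"))
        self.group = row.get("group", "")
        self.maternal = read_beats(base / row["maternal_file"],
                                   subject_id=str(self.mother_id),
                                   role="maternal")
        self.fetal = read_beats(base / row["fetal_file"],
                                subject_id=str(self.fetus_id), role="fetal")


def analyze_manifest(manifest_path, config: SimilarityConfig | None = None,
                     quality: QualityConfig | None = None,
                     n_epochs: int = 2) -> pd.DataFrame:
    """Score every dyad listed in a manifest CSV.

    The manifest has columns ``mother_id, fetus_id, ed, group,
    maternal_file, fetal_file`` with file paths relative to the manifest.
    A dyad whose files are missing or unreadable is flagged excluded and
    the run continues.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    records = []
    failed_rows = []
    for _, row in manifest.iterrows():
        try:
            records.append(_FileDyad(row, base))
        except (IngestError, OSError) as e:
            log.warning("dyad %s/%s unreadable: %s", row["mother_id"],
                        row["fetus_id"], e)
            failed_rows.append({
                "mother_id": row["mother_id"], "fetus_id": row["fetus_id"],
                "epoch_index": -1, "ed": row.get("ed", float("nan")),
                "group": row.get("group", ""), "cc1": float("nan"),
                "cc2": float("nan"), "clf": float("nan"), "chf": float("nan"),
                "n_valid_windows": 0, "excluded": True})
    scores = analyze_records(records, config, quality, n_epochs)
    if failed_rows:
        scores = pd.concat([scores, pd.DataFrame(failed_rows)],
                           ignore_index=True)
    return scores
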