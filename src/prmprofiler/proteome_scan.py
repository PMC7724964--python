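"""Scan protein sequences with finalized specificity profiles.

Every length-matched window is scored by summing the profile weights of its
residues, normalized by the profile's maximum attainable score, so the
relative score lies in [0, 1] and the column-wise consensus scores exactly 1.
Standard residues absent from the profile alphabet (e.g. Cys against a
phage-library profile) contribute zero weight; windows containing
non-standard letters are skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import STANDARD_RESIDUES
from .errors import FormatError
from .profile_builder import SpecificityProfile


@dataclass(frozen=True)
class ScanHit:
    """One window of a protein matching a profile."""

    protein_id: str
    start: int  # 1-based inclusive
    end: int
    matched_window: str
    raw_score: float
    rel_score: float
    profile_id: str


def scan_sequence(
    seq: str,
    profile: SpecificityProfile,
    min_rel_score: float = 0.7,
    protein_id: str = "",
    anchor_c_terminal: bool = False,
) -> list[ScanHit]:
    """Score every window of ``seq`` against the profile.

    Hits with relative score >= ``min_rel_score`` are returned sorted by
    relative score descending, ties by start coordinate ascending. With
    ``anchor_c_terminal`` only the window ending at the sequence end is
    considered (for profiles of termini-binding families).
    """
    if not profile.finalized:
        raise ValueError(f"{profile.prm_id}: profile not finalized")
    L = profile.n_positions
    seq = seq.upper()
    if L == 0:
        return []
    if len(seq) < L:
        warnings.warn(
            f"{protein_id or 'sequence'} shorter than profile ({len(seq)} < {L}); no hits"
        )
        return []
    index = {a: i for i, a in enumerate(profile.alphabet)}
    # summed in the same order as a window's per-column gather, so the
    # column-wise argmax window scores exactly 1.0
    max_score = float(np.sum(profile.w.max(axis=0)))
    if max_score <= 0:
        return []
    starts = (
        [len(seq) - L] if anchor_c_terminal else range(len(seq) - L + 1)
    )
    hits = []
    for s in starts:
        window = seq[s : s + L]
        if any(c not in STANDARD_RESIDUES for c in window):
            continue  # non-standard residue: window not scorable
        contrib = np.array(
            [
                profile.w[index[c], j] if c in index else 0.0
                for j, c in enumerate(window)
            ]
        )
        raw = float(np.sum(contrib))
        rel = raw / max_score
        if rel >= min_rel_score:
            hits.append(
                ScanHit(
                    protein_id=protein_id,
                    start=s + 1,
                    end=s + L,
                    matched_window=window,
                    raw_score=float(raw),
                    rel_score=float(rel),
                    profile_id=profile.prm_id,
                )
            )
    hits.sort(key=lambda h: (-h.rel_score, h.start))
    return hits


def scan_proteome(
    fasta: str | Path | Iterable[tuple[str, str]],
    profiles: Sequence[SpecificityProfile] | SpecificityProfile,
    min_rel_score: float = 0.7,
    top_k: int | None = None,
    anchor_c_terminal: bool = False,
) -> dict[str, pd.DataFrame]:
    """Scan a FASTA proteome with one or more profiles.

    Returns one hit table per profile id, each capped at ``top_k`` rows.
    ``fasta`` may also be an iterable of (id, sequence) pairs.
    """
    if isinstance(profiles, SpecificityProfile):
        profiles = [profiles]
    if isinstance(fasta, (str, Path)):
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(fasta), "fasta")]
    else:
        records = [(pid, str(s)) for pid, s in fasta]
    seen = set()
    for pid, _ in records:
        if pid in seen:
            raise FormatError(f"duplicate FASTA id {pid!r}")
        seen.add(pid)

    columns = ["protein_id", "start", "end", "matched_window", "raw_score",
               "rel_score", "profile_id"]
    tables: dict[str, pd.DataFrame] = {}
    for profile in profiles:
        hits: list[ScanHit] = []
        for pid, seq in records:
            hits.extend(
                scan_sequence(
                    seq,
                    profile,
                    min_rel_score=min_rel_score,
                    protein_id=pid,
                    anchor_c_terminal=anchor_c_terminal,
                )
            )
        hits.sort(key=lambda h: (-h.rel_score, h.protein_id, h.start))
        if top_k is not None:
            hits = hits[:top_k]
        tables[profile.prm_id] = pd.DataFrame(
            [h.__dict__ for h in hits], columns=columns
        )
    return tables
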