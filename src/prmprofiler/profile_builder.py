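"""Build PRM specificity profiles from selected peptides.

The pipeline mirrors how phage-selection data are turned into binding-site
models in this field:

1. peptides are clustered on shared ungapped k-mer seeds and aligned gap-free
   by the offset that anchors the seed (short linear motifs are contiguous,
   so no internal gaps are ever introduced);
2. peptides sharing no seed with enough of the set are removed as outliers
   (presumed to bind a different site or in a different mode);
3. the alignment becomes a weighted position weight matrix where the weight
   of residue *i* at position *j* is

       W_ij = f_ij * (max_i f_ij - min_i f_ij)

   with the minimum taken over the full alphabet, so a column missing any
   residue has min = 0;
4. the specificity potential SP_j = sum_i W_ij quantifies per-position
   selectivity (1 = a single residue tolerated, 0 = no preference), and is
   algebraically equal to max_i f_ij - min_i f_ij;
5. if the terminal column of the randomized region is specific, the invariant
   glycine linker flanking the library insert is made explicit by appending an
   all-Gly column;
6. terminal positions with SP < 0.2 are trimmed and the total specificity
   potential SPt sums SP over the remaining positions with SP >= 0.2.

Profiles with n >= 5 aligned peptides and SPt > 1 are considered reliable.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alphabet import ALPHABET_NO_CYS, PAD, resolve_alphabet
from .errors import InsufficientDataError
from .peptide_io import PeptideRecord, PeptideSet


@dataclass
class GapFreeAlignment:
    """Offset-only (gap-free) alignment of a PRM's peptides.

    ``offsets[p]`` is how far row *p* is shifted left relative to the
    alignment frame: a peptide with offset *o* starts at column
    ``max(offsets) - o``. Pad characters occur only at row ends.
    """

    prm_id: str
    rows: list[str]
    offsets: list[int]
    records: list[PeptideRecord]
    outliers: list[tuple[PeptideRecord, str]] = field(default_factory=list)

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def __post_init__(self):
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("alignment rows differ in length")
        for r in self.rows:
            if PAD in r.strip(PAD):
                raise ValueError(f"internal gap in row {r!r}")


@dataclass
class SpecificityProfile:
    """A weighted PWM with per-position specificity scores.

    ``f`` and ``w`` are (alphabet x positions) arrays; ``sp`` the per-position
    specificity potential. After :func:`trim_and_score`, the arrays cover the
    retained window only, ``trim`` records that window in pre-trim
    coordinates, ``spt`` holds the total specificity potential and
    ``classes`` the specific/non-specific label per retained position.
    """

    prm_id: str
    alphabet: tuple[str, ...]
    f: np.ndarray
    w: np.ndarray
    sp: np.ndarray | None = None
    spt: float | None = None
    classes: tuple[str, ...] = ()
    trim: tuple[int, int] = (0, 0)
    gly_flank: dict = field(default_factory=lambda: {"N": False, "C": False})
    alignment: GapFreeAlignment | None = None
    n_peptides: int = 0
    n_outliers: int = 0
    flags: tuple[str, ...] = ()

    @property
    def n_positions(self) -> int:
        return self.f.shape[1] if self.f.size else 0

    @property
    def finalized(self) -> bool:
        return self.spt is not None

    @property
    def is_empty(self) -> bool:
        return self.n_positions == 0

    def consensus(self) -> str:
        """Modal residue per position."""
        return "".join(self.alphabet[i] for i in self.f.argmax(axis=0))


# --- clustering and gap-free alignment --------------------------------------

def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _range_score(rows_with_starts, alphabet) -> float:
    """Merge objective: depth-squared-weighted column-frequency ranges.

    The weight rewards both conservation (the range max f - min f) and
    stacking rows in the same columns (depth squared); a plain sum of ranges
    would prefer placing clusters side by side, since every column covered by
    a single row already has range 1.
    """
    lo = min(s for _, s in rows_with_starts)
    hi = max(s + len(seq) for seq, s in rows_with_starts)
    index = {a: i for i, a in enumerate(alphabet)}
    counts = np.zeros((len(alphabet), hi - lo), dtype=float)
    for seq, s in rows_with_starts:
        for i, c in enumerate(seq):
            if c in index:
                counts[index[c], s - lo + i] += 1
    depth = counts.sum(axis=0)
    safe = np.maximum(depth, 1)
    f = counts / safe
    rng = f.max(axis=0) - f.min(axis=0)
    return float((depth**2 * rng).sum())


def cluster_and_align(
    peptides: PeptideSet | Sequence[PeptideRecord],
    min_motif_len: int = 3,
    outlier_fraction: float = 0.10,
    alphabet: Sequence[str] | str = "no-cys",
    override_alignment: Mapping[str, int] | None = None,
) -> GapFreeAlignment:
    """Cluster peptides on shared k-mer seeds and align them without gaps.

    Peptides are grouped by shared ungapped k-mers (k = ``min_motif_len``),
    each group is aligned by anchoring its seed, and groups are merged at the
    relative offset maximizing the summed column-frequency ranges. A peptide
    sharing no seed with at least ``ceil(outlier_fraction * n)`` other
    peptides is flagged as an outlier and excluded from the alignment.

    ``override_alignment`` (sequence -> start column) replaces the heuristic
    entirely for curated alignments; peptides absent from the mapping become
    outliers.
    """
    if isinstance(peptides, PeptideSet):
        prm_id = peptides.prm_id
        records = list(peptides.records)
    else:
        records = list(peptides)
        prm_id = records[0].prm_id if records else ""
    n = len(records)
    if n < 2:
        raise InsufficientDataError(
            f"{prm_id}: need at least 2 peptides to align, got {n}"
        )
    alphabet = resolve_alphabet(alphabet)
    k = min_motif_len

    if override_alignment is not None:
        kept, starts, outliers = [], [], []
        for rec in records:
            if rec.sequence in override_alignment:
                kept.append(rec)
                starts.append(int(override_alignment[rec.sequence]))
            else:
                outliers.append((rec, "not in override alignment"))
        if not kept:
            raise InsufficientDataError(f"{prm_id}: override alignment kept no peptides")
        return _finish_alignment(prm_id, kept, starts, outliers)

    seqs = [r.sequence for r in records]
    kmer_sets = [_kmers(s, k) for s in seqs]
    kmer_owners: dict[str, set[int]] = defaultdict(set)
    for p, ks in enumerate(kmer_sets):
        for km in ks:
            kmer_owners[km].add(p)

    threshold = math.ceil(outlier_fraction * n)
    support = [
        max((len(kmer_owners[km]) - 1 for km in kmer_sets[p]), default=0)
        for p in range(n)
    ]
    inliers = [p for p in range(n) if support[p] >= threshold]
    outliers = [
        (records[p], f"shares no seed with >= {threshold} other peptides")
        for p in range(n)
        if support[p] < threshold
    ]
    if not inliers:
        warnings.warn(
            f"{prm_id}: no peptides share seeds; keeping the first peptide only"
        )
        first = outliers.pop(0)[0]
        idx = records.index(first)
        inliers = [idx]

    # greedy seed cover: repeatedly anchor the k-mer present in most
    # unclustered peptides
    unclustered = set(inliers)
    clusters: list[dict[int, int]] = []  # peptide index -> start col (cluster frame)
    while len(unclustered) > 1:
        scored = [
            (-len(owners & unclustered), km)
            for km, owners in kmer_owners.items()
            if len(owners & unclustered) >= 2
        ]
        if not scored:
            break
        _, best_km = min(scored)  # max coverage, ties to lexicographic smallest
        members = sorted(kmer_owners[best_km] & unclustered)
        anchors = {p: seqs[p].find(best_km) for p in members}
        amax = max(anchors.values())
        clusters.append({p: amax - a for p, a in anchors.items()})
        unclustered -= set(members)
    for p in sorted(unclustered):
        clusters.append({p: 0})

    # merge clusters at the offset maximizing summed column-frequency ranges
    clusters.sort(key=lambda c: (-len(c), min(c)))
    merged = clusters[0]
    for c in clusters[1:]:
        cur_rows = [(seqs[p], s) for p, s in merged.items()]
        c_rows = [(seqs[p], s) for p, s in c.items()]
        cur_w = max(s + len(r) for r, s in cur_rows) - min(s for _, s in cur_rows)
        c_w = max(s + len(r) for r, s in c_rows) - min(s for _, s in c_rows)
        best = None
        for d in range(-(c_w - 1), cur_w):
            trial = cur_rows + [(r, s + d) for r, s in c_rows]
            score = _range_score(trial, alphabet)
            key = (-score, abs(d), d)
            if best is None or key < best[0]:
                best = (key, d)
        d = best[1]
        merged = dict(merged)
        merged.update({p: s + d for p, s in c.items()})

    order = sorted(merged)  # input order
    kept = [records[p] for p in order]
    starts = [merged[p] for p in order]
    return _finish_alignment(prm_id, kept, starts, outliers)


def _finish_alignment(prm_id, kept, starts, outliers) -> GapFreeAlignment:
    lo = min(starts)
    starts = [s - lo for s in starts]
    width = max(s + len(r.sequence) for r, s in zip(kept, starts))
    rows = [
        PAD * s + r.sequence + PAD * (width - s - len(r.sequence))
        for r, s in zip(kept, starts)
    ]
    smax = max(starts)
    offsets = [smax - s for s in starts]
    return GapFreeAlignment(
        prm_id=prm_id, rows=rows, offsets=offsets, records=kept, outliers=outliers
    )


# --- PWM, SP, flanking, trimming --------------------------------------------

def build_pwm(
    alignment: GapFreeAlignment,
    alphabet: Sequence[str] | str = "no-cys",
) -> SpecificityProfile:
    """Compute frequency and weight matrices from a gap-free alignment.

    Pads are excluded from column depth. The weight of residue *i* at
    position *j* is its frequency times the range between the most and least
    abundant residue at that position, the minimum taken over the full
    alphabet (so any absent residue pins the minimum at 0).
    """
    alphabet = resolve_alphabet(alphabet)
    if not alignment.rows:
        raise InsufficientDataError("empty alignment")
    index = {a: i for i, a in enumerate(alphabet)}
    counts = np.zeros((len(alphabet), alignment.width), dtype=float)
    for row in alignment.rows:
        for j, c in enumerate(row):
            if c == PAD:
                continue
            if c not in index:
                raise ValueError(
                    f"residue {c!r} in alignment is outside the profile alphabet"
                )
            counts[index[c], j] += 1
    depth = counts.sum(axis=0)
    empty = depth == 0
    if empty.any():
        warnings.warn(
            f"{alignment.prm_id}: dropping {int(empty.sum())} empty column(s)"
        )
        keep = ~empty
        counts = counts[:, keep]
        depth = depth[keep]
        alignment = replace(
            alignment,
            rows=["".join(r[j] for j in np.nonzero(keep)[0]) for r in alignment.rows],
        )
    f = counts / depth
    w = f * (f.max(axis=0) - f.min(axis=0))
    profile = SpecificityProfile(
        prm_id=alignment.prm_id,
        alphabet=alphabet,
        f=f,
        w=w,
        alignment=alignment,
        n_peptides=alignment.n_rows,
        n_outliers=len(alignment.outliers),
        trim=(0, f.shape[1]),
    )
    profile.sp = specificity_potential(profile)
    return profile


def specificity_potential(profile: SpecificityProfile) -> np.ndarray:
    """Per-position specificity potential: the column sums of the weights."""
    sp = profile.w.sum(axis=0)
    profile.sp = sp
    return sp


def glycine_flank(
    profile: SpecificityProfile, trigger: float = 0.33
) -> SpecificityProfile:
    """Make the library's invariant Gly linker explicit at specific termini.

    Randomized peptide inserts are flanked by glycine residues that can take
    part in recognition. If the extreme N- or C-terminal column is specific
    (SP >= ``trigger``), an all-Gly column is appended at that terminus for
    every row reaching it, and the PWM and SP are recomputed.
    """
    if profile.alignment is None:
        raise ValueError("glycine_flank requires the profile's alignment")
    sp = profile.sp if profile.sp is not None else specificity_potential(profile)
    if profile.is_empty:
        return profile
    add_n = bool(sp[0] >= trigger)
    add_c = bool(sp[-1] >= trigger)
    if not (add_n or add_c):
        return profile
    aln = profile.alignment
    rows = list(aln.rows)
    if add_n:
        rows = [("G" + r) if r[0] != PAD else (PAD + r) for r in rows]
    if add_c:
        rows = [(r + "G") if r[-1] != PAD else (r + PAD) for r in rows]
    new_aln = replace(aln, rows=rows)
    out = build_pwm(new_aln, profile.alphabet)
    out.gly_flank = {"N": add_n, "C": add_c}
    return out


def trim_and_score(
    profile: SpecificityProfile,
    trim_threshold: float = 0.2,
    class_threshold: float = 0.33,
) -> SpecificityProfile:
    """Trim weak terminal positions, compute SPt, and classify positions.

    Terminal positions with SP below ``trim_threshold`` are removed
    iteratively from both ends. SPt sums SP over the retained positions with
    SP >= ``trim_threshold`` (weak interior positions stay in the logo but do
    not count). Retained positions are labeled specific when SP >=
    ``class_threshold``.
    """
    sp = profile.sp if profile.sp is not None else specificity_potential(profile)
    keep = np.nonzero(sp >= trim_threshold)[0]
    if keep.size == 0:
        return replace(
            profile,
            f=profile.f[:, :0],
            w=profile.w[:, :0],
            sp=sp[:0],
            spt=0.0,
            classes=(),
            trim=(0, 0),
            flags=profile.flags + ("no significant profile",),
        )
    lo, hi = int(keep[0]), int(keep[-1]) + 1
    sp_t = sp[lo:hi]
    spt = float(sp_t[sp_t >= trim_threshold].sum())
    classes = tuple(
        "specific" if s >= class_threshold else "non-specific" for s in sp_t
    )
    return replace(
        profile,
        f=profile.f[:, lo:hi],
        w=profile.w[:, lo:hi],
        sp=sp_t,
        spt=spt,
        classes=classes,
        trim=(lo, hi),
    )


def build_profile(
    peptides: PeptideSet | Sequence[PeptideRecord],
    *,
    alphabet: Sequence[str] | str = "no-cys",
    min_motif_len: int = 3,
    outlier_fraction: float = 0.10,
    gly_trigger: float = 0.33,
    trim_threshold: float = 0.2,
    class_threshold: float = 0.33,
    collapse_duplicates: bool = True,
    add_gly_flank: bool = True,
    override_alignment: Mapping[str, int] | None = None,
) -> SpecificityProfile:
    """Run the full pipeline: align, weight, flank, trim, score."""
    if isinstance(peptides, PeptideSet) and collapse_duplicates:
        peptides = peptides.unique_records()
    aln = cluster_and_align(
        peptides,
        min_motif_len=min_motif_len,
        outlier_fraction=outlier_fraction,
        alphabet=alphabet,
        override_alignment=override_alignment,
    )
    profile = build_pwm(aln, alphabet)
    if add_gly_flank:
        profile = glycine_flank(profile, trigger=gly_trigger)
    return trim_and_score(
        profile, trim_threshold=trim_threshold, class_threshold=class_threshold
    )


def profile_gate(
    profiles: Iterable[SpecificityProfile],
    min_peptides: int = 5,
    min_spt: float = 1.0,
) -> list[SpecificityProfile]:
    """Keep profiles with enough aligned peptides (n >= 5) and SPt > 1."""
    kept = []
    for p in profiles:
        if not p.finalized:
            raise ValueError(f"{p.prm_id}: profile not finalized")
        if p.n_peptides >= min_peptides and p.spt > min_spt:
            kept.append(p)
    return kept
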