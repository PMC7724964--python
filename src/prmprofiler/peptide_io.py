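"""Readers, writers and core data types for peptide tables, motifs and regions.

The central container is the :class:`PeptideSet`: all peptides selected against
one peptide recognition module (PRM), together with provenance and optional
ELISA signals. Tables arrive as TSV with a header row; a column-mapping
``dialect`` lets differently-headed exports load without code changes.

Profiles built from peptide sets are serialized to a versioned JSON document
and, optionally, to MEME minimal motif format for use with standard motif
tools.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import STANDARD_RESIDUES
from .errors import FormatError, RecordError, UnsupportedPatternError

PROFILE_SCHEMA_VERSION = "1.0"

#: Default column mapping for peptide TSV tables (canonical name -> header).
DEFAULT_DIALECT: dict[str, str] = {
    "prm_id": "prm_id",
    "sequence": "sequence",
    "elisa": "elisa",
    "prm_family": "prm_family",
    "source": "source",
}


@dataclass(frozen=True)
class PeptideRecord:
    """One selected peptide: sequence, the PRM it bound, optional ELISA signal."""

    sequence: str
    prm_id: str
    elisa: float | None = None
    source: str = ""

    def __post_init__(self):
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise ValueError(
                f"illegal residue(s) {sorted(bad)} in sequence {self.sequence!r}"
            )
        if self.elisa is not None and self.elisa < 0:
            raise ValueError("ELISA signal must be non-negative")

    def validate_phage(self, expected_length: int | None = 16) -> None:
        """Check phage-library invariants: no Cys, fixed randomized-region length."""
        if "C" in self.sequence:
            raise ValueError(
                f"phage-derived peptide {self.sequence!r} contains Cys "
                "(excluded from the library)"
            )
        if expected_length is not None and len(self.sequence) != expected_length:
            raise ValueError(
                f"phage-derived peptide {self.sequence!r} has length "
                f"{len(self.sequence)}, expected {expected_length}"
            )


@dataclass
class PeptideSet:
    """All peptides selected against one PRM."""

    prm_id: str
    prm_family: str = ""
    records: list[PeptideRecord] = field(default_factory=list)

    def __post_init__(self):
        for r in self.records:
            if r.prm_id != self.prm_id:
                raise ValueError(
                    f"record prm_id {r.prm_id!r} does not match set {self.prm_id!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def unique_sequences(self) -> list[str]:
        """Distinct peptide sequences in first-seen order."""
        return list(dict.fromkeys(r.sequence for r in self.records))

    @property
    def n_unique(self) -> int:
        return len(self.unique_sequences)

    def unique_records(self) -> list[PeptideRecord]:
        """One record per distinct sequence (first occurrence kept).

        Unique peptides are the unit of analysis for profile building; the raw
        record count stays available on the set itself.
        """
        seen: dict[str, PeptideRecord] = {}
        for r in self.records:
            seen.setdefault(r.sequence, r)
        return list(seen.values())


@dataclass(frozen=True)
class DisorderedRegion:
    """A predicted intrinsically disordered region of a protein."""

    protein_id: str
    start: int  # 1-based inclusive
    end: int
    sequence: str

    def __post_init__(self):
        if self.start < 1:
            raise ValueError("start must be >= 1")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match coordinates "
                f"{self.start}-{self.end}"
            )


# --- ELM-style motifs -------------------------------------------------------

_CLASS_RE = re.compile(r"\[\^?[A-Z]+\]")
_UNSUPPORTED = re.compile(r"[(){}|*+?\\]|\.\{")


@dataclass(frozen=True)
class ElmMotif:
    """A SLiM class: a per-position regular expression plus known instances.

    Every pattern position is classifiable as *specific* (a literal residue, a
    character class, or a negated class — it prefers a subset of residues) or
    *wildcard* (``.`` — any substitution tolerated).
    """

    class_id: str
    pattern: str
    instances: tuple[str, ...] = ()
    position_classes: tuple[str, ...] = ()
    position_patterns: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.position_classes)

    @property
    def regex(self) -> re.Pattern:
        return re.compile("".join(self.position_patterns))

    def matches(self, sequence: str) -> bool:
        """True if *sequence* matches the motif position-for-position."""
        return self.regex.fullmatch(sequence) is not None


def parse_elm_motif(
    pattern: str,
    class_id: str = "",
    instances: Iterable[str] = (),
) -> ElmMotif:
    """Parse a restricted motif regex and classify each position.

    Grammar: residue literals, character classes ``[..]``, negated classes
    ``[^..]``, the wildcard ``.``, and the anchors ``^``/``$``. Quantifiers,
    alternation and grouping are rejected outright rather than partially
    supported.
    """
    if _UNSUPPORTED.search(pattern):
        raise UnsupportedPatternError(
            f"pattern {pattern!r} uses constructs outside the per-position grammar"
        )
    body = pattern
    if body.startswith("^"):
        body = body[1:]
    if body.endswith("$"):
        body = body[:-1]
    if "^" in body.replace("[^", "") or "$" in body:
        raise UnsupportedPatternError(f"misplaced anchor in {pattern!r}")

    tokens: list[str] = []
    i = 0
    while i < len(body):
        c = body[i]
        if c == "[":
            m = _CLASS_RE.match(body, i)
            if not m:
                raise UnsupportedPatternError(f"malformed class at offset {i} in {pattern!r}")
            tokens.append(m.group(0))
            i = m.end()
        elif c == ".":
            tokens.append(".")
            i += 1
        elif c.isalpha() and c.isupper() and c in STANDARD_RESIDUES:
            tokens.append(c)
            i += 1
        else:
            raise UnsupportedPatternError(
                f"unsupported character {c!r} at offset {i} in {pattern!r}"
            )
    classes = tuple("wildcard" if t == "." else "specific" for t in tokens)

    motif = ElmMotif(
        class_id=class_id,
        pattern=pattern,
        instances=tuple(str(s).upper() for s in instances),
        position_classes=classes,
        position_patterns=tuple(tokens),
    )
    for inst in motif.instances:
        if not motif.matches(inst):
            raise ValueError(
                f"instance {inst!r} does not match motif {pattern!r}"
            )
    return motif


# --- Peptide tables ---------------------------------------------------------

def read_peptide_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[PeptideSet]:
    """Load a TSV peptide table and group records into one PeptideSet per PRM.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    dialect
        Mapping from the canonical column names (``prm_id``, ``sequence``,
        and optionally ``elisa``, ``prm_family``, ``source``) to the headers
        used in the file. Defaults to the canonical names themselves.

    Record order within each set is preserved; sequences are uppercased.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for canonical in ("prm_id", "sequence"):
        if cols[canonical] not in df.columns:
            raise FormatError(
                f"required column {cols[canonical]!r} (for {canonical}) missing "
                f"from {path}"
            )
    has_elisa = cols["elisa"] in df.columns
    has_family = cols["prm_family"] in df.columns
    has_source = cols["source"] in df.columns

    sets: dict[str, PeptideSet] = {}
    for pos in range(len(df)):
        idx = pos + 2  # 1-based file line number; line 1 is the header
        row = df.iloc[pos]
        get = lambda name: str(row[cols[name]])
        prm_id = get("prm_id").strip()
        seq = get("sequence").strip().upper()
        elisa = None
        if has_elisa:
            raw = get("elisa").strip()
            if raw:
                try:
                    elisa = float(raw)
                except ValueError as e:
                    raise RecordError(f"unparseable ELISA value {raw!r}", row=idx) from e
        try:
            rec = PeptideRecord(
                sequence=seq,
                prm_id=prm_id,
                elisa=elisa,
                source=get("source").strip() if has_source else "",
            )
        except ValueError as e:
            raise RecordError(str(e), row=idx) from e
        if prm_id not in sets:
            sets[prm_id] = PeptideSet(
                prm_id=prm_id,
                prm_family=get("prm_family").strip() if has_family else "",
            )
        sets[prm_id].records.append(rec)
    return list(sets.values())


def write_peptide_table(sets: Iterable[PeptideSet], path: str | Path) -> None:
    """Write PeptideSets back to canonical TSV (inverse of read_peptide_table)."""
    rows = []
    for ps in sets:
        for r in ps.records:
            rows.append(
                {
                    "prm_id": r.prm_id,
                    "prm_family": ps.prm_family,
                    "sequence": r.sequence,
                    "elisa": "" if r.elisa is None else r.elisa,
                    "source": r.source,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta_regions(path: str | Path) -> list[DisorderedRegion]:
    """Read disordered regions from FASTA.

    Headers of the form ``>PROT|start-end`` carry coordinates; otherwise the
    region spans 1..len(sequence).
    """
    regions = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        m = re.fullmatch(r"(?P<pid>[^|]+)\|(?P<s>\d+)-(?P<e>\d+)", rec.id)
        if m:
            regions.append(
                DisorderedRegion(m["pid"], int(m["s"]), int(m["e"]), seq)
            )
        else:
            regions.append(DisorderedRegion(rec.id, 1, len(seq), seq))
    return regions


def write_fasta_regions(regions: Iterable[DisorderedRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f">{r.protein_id}|{r.start}-{r.end}\n{r.sequence}\n")


# --- Profile serialization --------------------------------------------------

def write_profile(profile, path: str | Path) -> None:
    """Serialize a finalized specificity profile to versioned JSON."""
    doc = profile_to_dict(profile)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def profile_to_dict(profile) -> dict:
    return {
        "schema_version": PROFILE_SCHEMA_VERSION,
        "prm_id": profile.prm_id,
        "alphabet": list(profile.alphabet),
        "n_positions": profile.n_positions,
        "frequencies": profile.f.tolist(),
        "weights": profile.w.tolist(),
        "sp": profile.sp.tolist(),
        "spt": profile.spt,
        "classes": list(profile.classes),
        "gly_flank": dict(profile.gly_flank),
        "trim": list(profile.trim),
        "n_peptides": profile.n_peptides,
        "n_outliers": profile.n_outliers,
    }


def read_profile(path: str | Path):
    """Read a profile JSON written by :func:`write_profile`."""
    from .profile_builder import SpecificityProfile  # deferred: avoids cycle

    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != PROFILE_SCHEMA_VERSION:
        warnings.warn(
            f"profile schema version {doc.get('schema_version')} != "
            f"{PROFILE_SCHEMA_VERSION}; attempting to read anyway"
        )
    return SpecificityProfile(
        prm_id=doc["prm_id"],
        alphabet=tuple(doc["alphabet"]),
        f=np.asarray(doc["frequencies"], dtype=float).reshape(
            len(doc["alphabet"]), doc["n_positions"]
        ),
        w=np.asarray(doc["weights"], dtype=float).reshape(
            len(doc["alphabet"]), doc["n_positions"]
        ),
        sp=np.asarray(doc["sp"], dtype=float),
        spt=doc["spt"],
        classes=tuple(doc["classes"]),
        gly_flank=dict(doc["gly_flank"]),
        trim=tuple(doc["trim"]),
        n_peptides=doc["n_peptides"],
        n_outliers=doc["n_outliers"],
        alignment=None,
    )


def write_meme(profiles, path: str | Path, background: Sequence[float] | None = None) -> None:
    """Export frequency matrices in MEME minimal motif format.

    One row per retained position; rows are renormalized over the profile's
    alphabet so each sums to 1 (MEME requires a proper distribution).
    """
    if not isinstance(profiles, (list, tuple)):
        profiles = [profiles]
    lines = ["MEME version 4", "", ""]
    if profiles:
        alpha = "".join(profiles[0].alphabet)
        lines[1] = f"ALPHABET= {alpha}"
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for p in profiles:
            fh.write(f"MOTIF {p.prm_id}\n")
            fh.write(
                f"letter-probability matrix: alength= {len(p.alphabet)} "
                f"w= {p.n_positions} nsites= {p.n_peptides}\n"
            )
            for j in range(p.n_positions):
                col = p.f[:, j]
                total = col.sum()
                col = col / total if total > 0 else col
                fh.write(" ".join(f"{x:.6f}" for x in col) + "\n")
            fh.write("\n")
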