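"""Reference window handling and per-sequence variant profiles.

The analysis operates on a short hypervariable fragment of the horse
mitochondrial control region (by default NPS 15,494-15,740, 247 bp).
Each aligned sequence is reduced to the set of differences it shows
against the reference bases of that window; all downstream machinery
(haplogroup motifs, haplotype networks, AMOVA distances) works on these
variant profiles rather than on raw sequences.

Variant labels follow the control-region convention: a bare NPS position
denotes a transition, a position with an A/C/G/T suffix a transversion,
suffix ``d`` a deletion and ``+`` an insertion after the given position
(e.g. ``15495+C``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_START = 15494
DEFAULT_WINDOW_END = 15740

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
GAP_CHARS = frozenset("-.")

#: IUPAC nucleotide ambiguity codes and their expansions.
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Recognised sample eras (modern surveys, ancient remains, wild horses).
ERAS = ("modern", "ancient_domestic", "ancient_no_date", "extinct_wild", "extant_wild")

#: Geographic region vocabulary used throughout the package.
REGIONS = ("NEA", "SEA", "CA", "WA", "SA", "NA", "EE", "SE", "CE", "NE", "WE",
           "AF", "NAM", "SAM")


@dataclass(frozen=True)
class ReferenceWindow:
    """An inclusive 1-based NPS coordinate window with its reference bases."""

    name: str
    ref_bases: str
    start_pos: int = DEFAULT_WINDOW_START
    end_pos: int = DEFAULT_WINDOW_END

    def __post_init__(self) -> None:
        if self.start_pos > self.end_pos:
            raise ValueError("window start_pos must not exceed end_pos")
        expected = self.end_pos - self.start_pos + 1
        if len(self.ref_bases) != expected:
            raise ValueError(
                f"ref_bases length {len(self.ref_bases)} does not match window span {expected}"
            )
        bad = set(self.ref_bases.upper()) - set("ACGT")
        if bad:
            raise ValueError(f"reference bases must be A/C/G/T, found {sorted(bad)}")
        object.__setattr__(self, "ref_bases", self.ref_bases.upper())

    @property
    def length(self) -> int:
        return self.end_pos - self.start_pos + 1

    def index_of(self, position: int) -> int:
        """0-based index in ``ref_bases`` for an NPS coordinate."""
        if not self.start_pos <= position <= self.end_pos:
            raise ValueError(f"position {position} outside window {self.start_pos}-{self.end_pos}")
        return position - self.start_pos

    @classmethod
    def from_fasta(cls, path: str | Path, name: str | None = None,
                   start_pos: int = DEFAULT_WINDOW_START,
                   end_pos: int = DEFAULT_WINDOW_END) -> "ReferenceWindow":
        record = next(SeqIO.parse(str(path), "fasta"))
        return cls(name=name or record.id, ref_bases=str(record.seq),
                   start_pos=start_pos, end_pos=end_pos)


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one sequenced individual."""

    sample_id: str
    population: str
    region: str
    era: str = "modern"

    def __post_init__(self) -> None:
        if self.era not in ERAS:
            raise ValueError(f"unknown era {self.era!r}; expected one of {ERAS}")


@dataclass(frozen=True)
class VariantCall:
    """A single difference against the reference window.

    ``alt`` holds the observed base (or inserted bases); it is empty for
    deletions.  The canonical ``label`` is derived from position, kind
    and alt and is what haplotype identity and motifs are built from.
    """

    position: int
    ref_base: str
    kind: str  # transition | transversion | deletion | insertion
    alt: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("transition", "transversion", "deletion", "insertion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == "deletion" and self.alt:
            raise ValueError("deletion calls carry no alt")
        if self.kind in ("transition", "transversion", "insertion") and not self.alt:
            raise ValueError(f"{self.kind} calls require an alt")

    @property
    def label(self) -> str:
        if self.kind == "transition":
            return str(self.position)
        if self.kind == "transversion":
            return f"{self.position}{self.alt}"
        if self.kind == "deletion":
            return f"{self.position}d"
        return f"{self.position}+{self.alt}"


@dataclass(frozen=True)
class HaplotypeProfile:
    """A sequence reduced to its variant calls against one window.

    ``missing_positions`` records NPS coordinates that could not be read
    (N or other fully ambiguous characters); they never generate calls
    and are excluded from pairwise comparison.
    """

    sample_id: str
    variants: frozenset[VariantCall]
    window_name: str = ""
    missing_positions: frozenset[int] = field(default_factory=frozenset)

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(v.label for v in self.variants)

    @property
    def canonical_key(self) -> str:
        ordered = sorted(self.variants, key=lambda v: (v.position, v.label))
        return ";".join(v.label for v in ordered)


def load_alignment(fasta_path: str | Path, metadata_path: str | Path
                   ) -> list[tuple[SampleRecord, str]]:
    """Read a pre-aligned FASTA plus a sample-metadata TSV.

    The TSV must have columns ``sample_id``, ``population``, ``region``
    and ``era``.  FASTA entries without metadata are excluded with a
    logged warning; all sequences must have equal length.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "population", "region", "era"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
    by_id = {row.sample_id: row for row in meta.itertuples(index=False)}

    out: list[tuple[SampleRecord, str]] = []
    length: int | None = None
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(
                f"alignment error: sequence {rec.id} has length {len(seq)}, expected {length}"
            )
        row = by_id.get(rec.id)
        if row is None:
            logger.warning("sample %s has no metadata row; excluded", rec.id)
            continue
        out.append((SampleRecord(row.sample_id, row.population, row.region, row.era), seq))
    return out


def trim_to_window(aligned_seq: str, window: ReferenceWindow, alignment_offset: int) -> str:
    """Slice an aligned sequence down to the analysis window.

    ``alignment_offset`` is the NPS coordinate of alignment column 1.
    Gap characters are preserved in the returned slice.
    """
    start = window.start_pos - alignment_offset
    stop = start + window.length
    if start < 0 or stop > len(aligned_seq):
        raise ValueError(
            f"window {window.start_pos}-{window.end_pos} outside alignment "
            f"(offset {alignment_offset}, length {len(aligned_seq)})"
        )
    return aligned_seq[start:stop]


def call_variants(window_seq: str, window: ReferenceWindow, sample_id: str = "") -> HaplotypeProfile:
    """Compare a window-length sequence against the reference.

    Transitions keep a bare-position label, transversions a base suffix,
    gaps become deletion calls.  An ambiguity code compatible with the
    reference base emits no call; N (and any code covering all four
    bases) marks the position as missing.
    """
    if len(window_seq) != window.length:
        raise ValueError(
            f"sequence length {len(window_seq)} does not match window length {window.length}"
        )
    calls: set[VariantCall] = set()
    missing: set[int] = set()
    for i, raw in enumerate(window_seq.upper()):
        pos = window.start_pos + i
        ref = window.ref_bases[i]
        if raw == ref:
            continue
        if raw in GAP_CHARS:
            calls.add(VariantCall(pos, ref, "deletion"))
            continue
        expansion = IUPAC.get(raw)
        if expansion is None:
            raise ValueError(f"non-IUPAC character {raw!r} at NPS {pos}")
        if len(expansion) == 4:
            missing.add(pos)
            continue
        if ref in expansion:
            # uncertain read compatible with the reference: no call
            continue
        ref_class = PURINES if ref in PURINES else PYRIMIDINES
        alt = next(iter(expansion)) if len(expansion) == 1 else raw
        if expansion <= ref_class:
            calls.add(VariantCall(pos, ref, "transition", alt=alt))
        else:
            # different base class (or a mixed-class ambiguity incompatible
            # with the reference): labelled with the observed base/code
            calls.add(VariantCall(pos, ref, "transversion", alt=alt))
    return HaplotypeProfile(sample_id=sample_id, variants=frozenset(calls),
                            window_name=window.name, missing_positions=frozenset(missing))


def reconstruct_sequence(profile: HaplotypeProfile, window: ReferenceWindow) -> str:
    """Rebuild the window sequence from reference + variants (+ missing as N)."""
    bases = list(window.ref_bases)
    for v in profile.variants:
        if v.kind == "insertion":
            raise ValueError("cannot place insertions in a fixed-length window sequence")
        i = window.index_of(v.position)
        bases[i] = "-" if v.kind == "deletion" else v.alt
    for pos in profile.missing_positions:
        bases[window.index_of(pos)] = "N"
    return "".join(bases)


def hamming_distance(profile_a: HaplotypeProfile, profile_b: HaplotypeProfile) -> int:
    """Number of mismatching variant labels between two profiles.

    The size of the symmetric difference of the label sets, skipping any
    variant whose position is missing in the other profile.  Indels count
    one mismatch per call.
    """
    if profile_a.window_name != profile_b.window_name:
        raise ValueError(
            f"profiles from different windows: {profile_a.window_name!r} vs {profile_b.window_name!r}"
        )
    d = 0
    for v in profile_a.variants:
        if v.position in profile_b.missing_positions:
            continue
        if v.label not in profile_b.labels:
            d += 1
    for v in profile_b.variants:
        if v.position in profile_a.missing_positions:
            continue
        if v.label not in profile_a.labels:
            d += 1
    return d


@dataclass
class CollapsedHaplotype:
    """One unique haplotype with its carriers and per-region counts."""

    canonical_key: str
    labels: frozenset[str]
    total_count: int
    region_counts: dict[str, int]
    carriers: list[str]
    haplogroup: str | None = None


def collapse_haplotypes(profiles: list[HaplotypeProfile],
                        records: list[SampleRecord],
                        haplogroups: dict[str, str] | None = None
                        ) -> list[CollapsedHaplotype]:
    """Group identical variant profiles into counted haplotypes.

    ``haplogroups`` optionally maps sample_id to a haplogroup label; a
    collapsed haplotype takes the majority label of its carriers.
    Returned list is sorted by canonical_key, so the result is invariant
    under input permutation.
    """
    by_id = {r.sample_id: r for r in records}
    grouped: dict[str, CollapsedHaplotype] = {}
    for p in profiles:
        rec = by_id.get(p.sample_id)
        if rec is None:
            raise ValueError(f"profile {p.sample_id} has no matching SampleRecord")
        key = p.canonical_key
        h = grouped.get(key)
        if h is None:
            h = CollapsedHaplotype(key, p.labels, 0, {}, [])
            grouped[key] = h
        h.total_count += 1
        h.region_counts[rec.region] = h.region_counts.get(rec.region, 0) + 1
        h.carriers.append(p.sample_id)
    out = [grouped[k] for k in sorted(grouped)]
    for h in out:
        h.carriers.sort()
        if haplogroups:
            votes: dict[str, int] = {}
            for sid in h.carriers:
                hg = haplogroups.get(sid)
                if hg is not None:
                    votes[hg] = votes.get(hg, 0) + 1
            if votes:
                h.haplogroup = max(sorted(votes), key=lambda k: votes[k])
    return out


def haplotypes_to_dataframe(haplotypes: list[CollapsedHaplotype]) -> pd.DataFrame:
    rows = []
    for h in haplotypes:
        rows.append({
            "canonical_key": h.canonical_key,
            "count": h.total_count,
            "haplogroup": h.haplogroup or "",
            "region_counts": ";".join(f"{r}:{c}" for r, c in sorted(h.region_counts.items())),
            "carriers": ";".join(h.carriers),
        })
    return pd.DataFrame(rows, columns=["canonical_key", "count", "haplogroup",
                                       "region_counts", "carriers"])
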