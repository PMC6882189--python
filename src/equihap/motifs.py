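"""Haplogroup motif inference and motif-based classification.

A haplogroup's *motif* is the set of variant labels exclusively shared
by all of its members within the analysis window.  Short control-region
fragments are assigned to haplogroups by matching these diagnostic
variants; when missing data or derived mutations erode an exact match,
a near-matching rule assigns the haplogroup whose motif is best covered,
subject to a minimum matched fraction and a margin over the runner-up.

Some backbone haplogroups carry no diagnostic variant inside a short
window at all; their motifs come back empty and such haplogroups can
never be assigned from the fragment alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .window import HaplotypeProfile, ReferenceWindow, SampleRecord

logger = logging.getLogger(__name__)

UNCLASSIFIED = "UNCLASSIFIED"

#: Default merge of older single-letter clade names into the hierarchical
#: nomenclature (E/F/G -> EFG, J/K -> KJ, O/P -> OP).
NOMENCLATURE_MERGES = {
    "E": "EFG", "F": "EFG", "G-sub": "EFG",
    "J": "KJ", "K": "KJ",
    "O": "OP", "P": "OP",
}


@dataclass(frozen=True)
class Motif:
    """Diagnostic variant labels of one haplogroup."""

    haplogroup: str
    diagnostic_variants: frozenset[str]
    training_support: int

    def __post_init__(self) -> None:
        if self.training_support < 1:
            raise ValueError("training_support must be >= 1")


@dataclass(frozen=True)
class HaplogroupCall:
    sample_id: str
    haplogroup: str
    matched_fraction: float
    margin: float
    mode: str  # exact_motif | near_match | unclassified


def _label_position(label: str) -> int:
    digits = ""
    for ch in label:
        if ch.isdigit():
            digits += ch
        else:
            break
    return int(digits)


def infer_motifs(labelled_profiles: list[tuple[HaplotypeProfile, str]],
                 window: ReferenceWindow | None = None,
                 rename_map: dict[str, str] | None = None) -> list[Motif]:
    """Derive per-haplogroup motifs from labelled training profiles.

    A variant belongs to haplogroup h's motif iff it is present in every
    training member of h that was observed at the position and absent
    from every member of every other haplogroup.  An optional rename map
    (e.g. ``NOMENCLATURE_MERGES``) is applied to labels first, so motifs
    are inferred for the merged haplogroups.
    """
    if rename_map:
        labelled_profiles = [(p, rename_map.get(hg, hg)) for p, hg in labelled_profiles]
    groups: dict[str, list[HaplotypeProfile]] = {}
    for profile, hg in labelled_profiles:
        groups.setdefault(hg, []).append(profile)
    if len(groups) < 2:
        raise ValueError("motif inference needs at least two haplogroup labels")
    for hg, members in groups.items():
        if not members:
            raise ValueError(f"haplogroup {hg} has no training members")

    def in_window(label: str) -> bool:
        if window is None:
            return True
        return window.start_pos <= _label_position(label) <= window.end_pos

    motifs: list[Motif] = []
    for hg in sorted(groups):
        members = groups[hg]
        union_labels: set[str] = set()
        for p in members:
            union_labels |= p.labels
        # a member unreadable at the position does not veto the variant
        shared = {
            lab for lab in union_labels
            if in_window(lab) and all(
                lab in p.labels or _label_position(lab) in p.missing_positions
                for p in members)
        }
        others: set[str] = set()
        for other_hg, other_members in groups.items():
            if other_hg == hg:
                continue
            for p in other_members:
                others |= p.labels
        diagnostic = frozenset(shared - others)
        if not diagnostic:
            logger.warning("haplogroup %s has no diagnostic motif within the window", hg)
        motifs.append(Motif(hg, diagnostic, training_support=len(members)))
    return motifs


def assign_haplogroup(profile: HaplotypeProfile, motifs: list[Motif],
                      min_fraction: float = 0.5,
                      min_margin: float = 1e-9) -> HaplogroupCall:
    """Assign one profile by motif (near-)matching.

    Each haplogroup is scored by the fraction of its motif variants
    present in the profile, counted over motif sites the profile was
    actually observed at (missing positions do not count against a
    match).  A score of 1 is an exact motif match; otherwise the best
    haplogroup wins if its score reaches ``min_fraction`` and beats the
    runner-up by at least ``min_margin``.
    """
    if not motifs:
        raise ValueError("no motifs supplied")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    scorable = [m for m in motifs if m.diagnostic_variants]
    if not scorable:
        raise ValueError("all motifs are empty; nothing can be assigned")

    scores: list[tuple[float, str]] = []
    for m in scorable:
        visible = {lab for lab in m.diagnostic_variants
                   if _label_position(lab) not in profile.missing_positions}
        if not visible:
            continue  # every motif site unreadable in this fragment
        frac = len(visible & profile.labels) / len(visible)
        scores.append((frac, m.haplogroup))
    if not scores:
        return HaplogroupCall(profile.sample_id, UNCLASSIFIED, 0.0, 0.0, "unclassified")

    scores.sort(key=lambda t: (-t[0], t[1]))
    best_frac, best_hg = scores[0]
    runner_up = scores[1][0] if len(scores) > 1 else 0.0
    margin = best_frac - runner_up

    if best_frac == 1.0:
        if len(scores) > 1 and scores[1][0] == 1.0:
            logger.warning("sample %s matches motifs of %s and %s exactly; conflict",
                           profile.sample_id, best_hg, scores[1][1])
            return HaplogroupCall(profile.sample_id, UNCLASSIFIED, 1.0, 0.0, "unclassified")
        return HaplogroupCall(profile.sample_id, best_hg, 1.0, margin, "exact_motif")
    if best_frac >= min_fraction and margin >= min_margin:
        return HaplogroupCall(profile.sample_id, best_hg, best_frac, margin, "near_match")
    return HaplogroupCall(profile.sample_id, UNCLASSIFIED, best_frac, margin, "unclassified")


def classify_dataset(profiles: list[HaplotypeProfile], motifs: list[Motif],
                     records: list[SampleRecord] | None = None,
                     min_fraction: float = 0.5,
                     min_margin: float = 1e-9
                     ) -> tuple[list[HaplogroupCall], pd.DataFrame]:
    """Classify every profile and tabulate counts per haplogroup.

    Returns the calls (one per input profile, input order preserved) and
    a summary table of counts per haplogroup per population and region
    (or a single overall column when no records are given).
    """
    calls = [assign_haplogroup(p, motifs, min_fraction, min_margin) for p in profiles]
    by_id = {r.sample_id: r for r in records} if records else {}
    rows = []
    for call in calls:
        rec = by_id.get(call.sample_id)
        rows.append({
            "sample_id": call.sample_id,
            "haplogroup": call.haplogroup,
            "population": rec.population if rec else "all",
            "region": rec.region if rec else "all",
        })
    df = pd.DataFrame(rows)
    summary = (df.groupby(["haplogroup", "population", "region"], sort=True)
                 .size().reset_index(name="count")
                 .sort_values(["haplogroup", "population", "region"])
                 .reset_index(drop=True))
    return calls, summary


def calls_to_dataframe(calls: list[HaplogroupCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample_id": c.sample_id, "haplogroup": c.haplogroup, "mode": c.mode,
          "matched_fraction": c.matched_fraction, "margin": c.margin} for c in calls],
        columns=["sample_id", "haplogroup", "mode", "matched_fraction", "margin"])


def motifs_to_json(motifs: list[Motif], path: str | Path) -> None:
    payload = [{"haplogroup": m.haplogroup,
                "diagnostic_variants": sorted(m.diagnostic_variants),
                "training_support": m.training_support} for m in motifs]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def motifs_from_json(path: str | Path) -> list[Motif]:
    payload = json.loads(Path(path).read_text())
    return [Motif(d["haplogroup"], frozenset(d["diagnostic_variants"]),
                  d["training_support"]) for d in payload]
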