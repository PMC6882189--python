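"""Haplogroup-structured synthetic control-region datasets.

Generates aligned window-length sequences with known truth so every
pipeline stage is testable without real survey data.  The model is
deliberately simple but mirrors the structure the analyses rely on:

* each haplogroup descends from a founder haplotype carrying a private
  mutation motif (``motif_size`` variants at positions used by no other
  haplogroup, so motif exclusivity holds by construction);
* within a haplogroup, samples radiate in a star from the founder: each
  sample adds Poisson(``mutation_rate``) private derived mutations at
  positions untouched by any founder (within-lineage infinite sites);
* populations draw their samples' haplogroups from configured frequency
  vectors, emulating region-differentiated haplogroup profiles such as
  the published north vs south East-Asia contrast;
* ``dropout_rate`` emulates incompletely read fragments (the
  ancient-DNA regime): each motif site of a sample is independently
  replaced by missing data ('N') with this probability.

Mutations are transition-biased 10:1, the dominant pattern in
hypervariable control-region evolution.  All randomness flows from a
single master seed through named substreams, so outputs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .window import (
    HaplotypeProfile,
    ReferenceWindow,
    SampleRecord,
    VariantCall,
    reconstruct_sequence,
)

PURINE_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

#: Pooled haplogroup frequencies of the published northern and southern
#: East-Asia cohorts, used as the default population profiles.
NEA_FREQUENCIES = {"D": 0.071, "I": 0.065, "EFG": 0.147, "H": 0.022, "L": 0.189,
                   "M": 0.055, "N": 0.063, "OP": 0.132, "Q": 0.234, "R": 0.022}
SEA_FREQUENCIES = {"D": 0.067, "I": 0.026, "EFG": 0.124, "H": 0.048, "L": 0.332,
                   "M": 0.117, "N": 0.007, "OP": 0.082, "Q": 0.132, "R": 0.065}


@dataclass(frozen=True)
class HaplogroupSpec:
    name: str
    motif_size: int = 3
    mutation_rate: float = 0.5  # Poisson mean of derived mutations per sample

    def __post_init__(self) -> None:
        if self.motif_size < 1:
            raise ValueError("motif_size must be >= 1")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")


@dataclass(frozen=True)
class PopulationSpec:
    code: str
    region: str
    n: int
    frequencies: dict[str, float]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies of {self.code} sum to {total}, not 1")


@dataclass
class SimulationConfig:
    seed: int
    haplogroups: list[HaplogroupSpec]
    populations: list[PopulationSpec]
    window: ReferenceWindow | None = None  # None: a random reference is drawn
    divergence: float = 0.0  # extra private founder mutations (Poisson mean)
    dropout_rate: float = 0.0
    transition_fraction: float = 10.0 / 11.0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        names = {h.name for h in self.haplogroups}
        for pop in self.populations:
            unknown = set(pop.frequencies) - names
            if unknown:
                raise ValueError(f"population {pop.code} references unknown "
                                 f"haplogroups {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "divergence": self.divergence,
            "dropout_rate": self.dropout_rate,
            "transition_fraction": self.transition_fraction,
            "window": None if self.window is None else {
                "name": self.window.name,
                "start_pos": self.window.start_pos,
                "end_pos": self.window.end_pos,
            },
            "haplogroups": [{"name": h.name, "motif_size": h.motif_size,
                             "mutation_rate": h.mutation_rate}
                            for h in self.haplogroups],
            "populations": [{"code": p.code, "region": p.region, "n": p.n,
                             "frequencies": dict(sorted(p.frequencies.items()))}
                            for p in self.populations],
        }


def default_config(seed: int, n_per_population: int = 50,
                   dropout_rate: float = 0.0,
                   mutation_rate: float = 0.5,
                   motif_size: int = 3) -> SimulationConfig:
    """A two-cohort study design: northern vs southern East Asia.

    Ten haplogroups with three-site motifs; two populations per cohort
    drawing from the pooled published cohort frequency profiles.
    """
    hgs = [HaplogroupSpec(name, motif_size, mutation_rate)
           for name in ("D", "I", "EFG", "H", "L", "M", "N", "OP", "Q", "R")]
    pops = [
        PopulationSpec("NEA1", "NEA", n_per_population, NEA_FREQUENCIES),
        PopulationSpec("NEA2", "NEA", n_per_population, NEA_FREQUENCIES),
        PopulationSpec("SEA1", "SEA", n_per_population, SEA_FREQUENCIES),
        PopulationSpec("SEA2", "SEA", n_per_population, SEA_FREQUENCIES),
    ]
    return SimulationConfig(seed=seed, haplogroups=hgs, populations=pops,
                            dropout_rate=dropout_rate)


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ("reference", "founders", "samples")
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def random_reference(rng: np.random.Generator,
                     start_pos: int = 15494, end_pos: int = 15740,
                     name: str = "synthetic_reference") -> ReferenceWindow:
    bases = rng.choice(list("ACGT"), size=end_pos - start_pos + 1)
    return ReferenceWindow(name=name, ref_bases="".join(bases),
                           start_pos=start_pos, end_pos=end_pos)


def _draw_variant(position: int, ref: str, rng: np.random.Generator,
                  transition_fraction: float) -> VariantCall:
    if rng.random() < transition_fraction:
        return VariantCall(position, ref, "transition", alt=PURINE_PARTNER[ref])
    alt = TRANSVERSIONS[ref][rng.integers(2)]
    return VariantCall(position, ref, "transversion", alt=alt)


def simulate_founders(config: SimulationConfig,
                      rng: np.random.Generator | None = None,
                      window: ReferenceWindow | None = None
                      ) -> dict[str, HaplotypeProfile]:
    """Draw founder haplotypes with mutually exclusive motifs.

    Motif positions are sampled without replacement across all
    haplogroups, so no diagnostic variant can be shared.  Optional
    ``divergence`` adds further private founder mutations the same way.
    """
    streams = _substreams(config.seed)
    if rng is None:
        rng = streams["founders"]
    if window is None:
        window = config.window or random_reference(streams["reference"])

    n_motif = sum(h.motif_size for h in config.haplogroups)
    extras = [int(rng.poisson(config.divergence)) for _ in config.haplogroups] \
        if config.divergence > 0 else [0] * len(config.haplogroups)
    needed = n_motif + sum(extras)
    if needed > window.length:
        raise ValueError(f"window of {window.length} bp cannot host {needed} "
                         "exclusive founder variants")
    positions = rng.choice(np.arange(window.start_pos, window.end_pos + 1),
                           size=needed, replace=False)
    founders: dict[str, HaplotypeProfile] = {}
    cursor = 0
    for spec, extra in zip(config.haplogroups, extras):
        calls = set()
        for _ in range(spec.motif_size + extra):
            pos = int(positions[cursor])
            cursor += 1
            ref = window.ref_bases[window.index_of(pos)]
            calls.add(_draw_variant(pos, ref, rng, config.transition_fraction))
        founders[spec.name] = HaplotypeProfile(
            sample_id=f"founder_{spec.name}", variants=frozenset(calls),
            window_name=window.name)
    return founders


@dataclass
class SimulatedDataset:
    window: ReferenceWindow
    founders: dict[str, HaplotypeProfile]
    records: list[SampleRecord]
    sequences: dict[str, str]     # sample_id -> window sequence
    profiles: list[HaplotypeProfile]
    truth: dict[str, str]         # sample_id -> planted haplogroup
    config: SimulationConfig = field(repr=False, default=None)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "sequences.fasta"
        with fasta.open("w") as fh:
            for rec in self.records:
                fh.write(f">{rec.sample_id}\n{self.sequences[rec.sample_id]}\n")
        metadata = outdir / "metadata.tsv"
        pd.DataFrame(
            [{"sample_id": r.sample_id, "population": r.population,
              "region": r.region, "era": r.era} for r in self.records]
        ).to_csv(metadata, sep="\t", index=False)
        truth = outdir / "truth.tsv"
        pd.DataFrame(
            [{"sample_id": r.sample_id, "haplogroup": self.truth[r.sample_id]}
             for r in self.records]
        ).to_csv(truth, sep="\t", index=False)
        reference = outdir / "reference.fasta"
        reference.write_text(f">{self.window.name}\n{self.window.ref_bases}\n")
        echo = outdir / "config-echo.yaml"
        echo.write_text(yaml.safe_dump(self.config.to_dict(), sort_keys=True))
        return {"fasta": fasta, "metadata": metadata, "truth": truth,
                "reference": reference, "config": echo}


def simulate_samples(config: SimulationConfig) -> SimulatedDataset:
    """Draw the full dataset: founders, then samples population by population."""
    streams = _substreams(config.seed)
    window = config.window or random_reference(streams["reference"])
    founders = simulate_founders(config, rng=streams["founders"], window=window)
    rng = streams["samples"]

    founder_positions = {v.position for f in founders.values() for v in f.variants}
    free_positions = np.array(sorted(
        set(range(window.start_pos, window.end_pos + 1)) - founder_positions))
    rate_of = {h.name: h.mutation_rate for h in config.haplogroups}
    hg_names = [h.name for h in config.haplogroups]

    records, profiles = [], []
    sequences: dict[str, str] = {}
    truth: dict[str, str] = {}
    for pop in config.populations:
        probs = np.array([pop.frequencies.get(name, 0.0) for name in hg_names])
        assigned = rng.choice(len(hg_names), size=pop.n, p=probs / probs.sum())
        for i, hg_idx in enumerate(assigned):
            hg = hg_names[int(hg_idx)]
            sample_id = f"{pop.code}_{i + 1:04d}"
            calls = set(founders[hg].variants)
            missing: set[int] = set()
            if config.dropout_rate > 0:
                for v in founders[hg].variants:
                    if rng.random() < config.dropout_rate:
                        calls.discard(v)
                        missing.add(v.position)
            n_extra = int(rng.poisson(rate_of[hg]))
            if n_extra > 0:
                picks = rng.choice(free_positions, size=min(n_extra, len(free_positions)),
                                   replace=False)
                for pos in picks:
                    ref = window.ref_bases[window.index_of(int(pos))]
                    calls.add(_draw_variant(int(pos), ref, rng,
                                            config.transition_fraction))
            profile = HaplotypeProfile(sample_id=sample_id, variants=frozenset(calls),
                                       window_name=window.name,
                                       missing_positions=frozenset(missing))
            records.append(SampleRecord(sample_id, pop.code, pop.region, "modern"))
            profiles.append(profile)
            sequences[sample_id] = reconstruct_sequence(profile, window)
            truth[sample_id] = hg
    return SimulatedDataset(window=window, founders=founders, records=records,
                            sequences=sequences, profiles=profiles, truth=truth,
                            config=config)
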