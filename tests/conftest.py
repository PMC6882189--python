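import numpy as np
import pytest
from hypothesis import settings

from equihap.window import HaplotypeProfile, ReferenceWindow, VariantCall

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_window() -> ReferenceWindow:
    """A 20 bp window at NPS 15494-15513 with a fixed reference."""
    return ReferenceWindow(name="ref", ref_bases="ACGTACGTACGTACGTACGT",
                           start_pos=15494, end_pos=15513)


def make_profile(sample_id: str, labels, window_name: str = "w",
                 missing=()) -> HaplotypeProfile:
    """Build a profile from canonical labels (bare=transition, base
    suffix=transversion, 'd'=deletion, '+'=insertion)."""
    calls = []
    for lab in labels:
        if "+" in lab:
            pos, alt = lab.split("+")
            calls.append(VariantCall(int(pos), "A", "insertion", alt))
        elif lab.endswith("d"):
            calls.append(VariantCall(int(lab[:-1]), "A", "deletion"))
        elif lab[-1] in "ACGT" and not lab[-1].isdigit():
            calls.append(VariantCall(int(lab[:-1]), "G", "transversion", lab[-1]))
        else:
            calls.append(VariantCall(int(lab), "A", "transition", "G"))
    return HaplotypeProfile(sample_id, frozenset(calls), window_name,
                            frozenset(missing))


def random_label_profiles(rng: np.random.Generator, n: int, n_sites: int = 20,
                          p: float = 0.25, window_name: str = "w"):
    """n profiles with independent Bernoulli(p) transition variants."""
    out = []
    for i in range(n):
        labels = [str(15500 + s) for s in range(n_sites) if rng.random() < p]
        out.append(make_profile(f"s{i}", labels, window_name))
    return out
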