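import pytest

from cgr.genome import make_toy_genome
from cgr.simulate import make_replicative_case


@pytest.fixture(scope="session")
def toy_genome():
    """A small three-chromosome genome shared by read-only tests."""
    return make_toy_genome(3, [80_000, 60_000, 50_000], 0.41, seed=7)


@pytest.fixture(scope="session")
def basic_truth():
    """One basic-insertion ground truth (donor duplication copied into a
    deleted acceptor interval)."""
    return make_replicative_case(11, preset="basic")


@pytest.fixture(scope="session")
def chromo_truth():
    """One iterative-template-switch ground truth with a templated insert."""
    return make_replicative_case(12, preset="chromoanasynthesis")


def merge_walk(walk):
    """Collapse reference-adjacent same-orientation runs so walks from the
    simulator and from graph reconstruction are comparable."""
    out = []
    for (chrom, s, e), o in walk:
        if out:
            (pc, ps, pe), po = out[-1]
            if pc == chrom and po == o:
                if o == "+" and s == pe + 1:
                    out[-1] = ((pc, ps, e), o)
                    continue
                if o == "-" and e == ps - 1:
                    out[-1] = ((pc, s, pe), o)
                    continue
        out.append(((chrom, s, e), o))
    return tuple(out)


def rc_walk(walk):
    return tuple((seg, "+" if o == "-" else "-") for seg, o in reversed(walk))
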