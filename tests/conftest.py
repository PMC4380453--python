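import numpy as np
import pytest

import sh3screen as s

AA = "ACDEFGHIKLMNPQRSTVWY"
HYDRO = set("AVLIMFWYP")
BASIC = set("KR")


def expand_symbol(sym):
    if sym == "x":
        return set(AA)
    if sym == "+":
        return set(BASIC)
    if sym in ("h", "Φ"):
        return set(HYDRO)
    return {sym}


def brute_force_scan(sequence, spec):
    """Character-by-character window matcher, independent of the package
    scanner.  Returns 1-based start positions of every (overlapping) match."""
    sets = [expand_symbol(c) for c in spec]
    L = len(sets)
    out = []
    for i in range(len(sequence) - L + 1):
        if all(sequence[i + j] in sets[j] for j in range(L)):
            out.append(i + 1)
    return out


def naive_average_linkage(D):
    """O(n^3) unweighted average-linkage agglomeration on a full distance
    matrix; returns the sorted list of merge heights."""
    n = D.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if d < best[0]:
                    best = (d, (a, b))
        d, (a, b) = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return sorted(heights)


def random_sequence(rng, length):
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture(scope="session")
def fixture_tables():
    return s.load_fixture()


@pytest.fixture(scope="session")
def printed_tails(fixture_tables):
    return {t.id: t for t in fixture_tables.tails}


@pytest.fixture(scope="session")
def patterns():
    return s.default_patterns()


@pytest.fixture(scope="session")
def pattern_specs():
    """Raw spec strings of the shipped grammar, for the brute-force oracle."""
    import yaml
    from importlib.resources import files

    with open(str(files("sh3screen.data") / "patterns.yaml")) as fh:
        return yaml.safe_load(fh)
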