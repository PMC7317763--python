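"""Independent brute-force oracles used by the test suite only."""

import numpy as np
from Bio.Seq import Seq


def fourfold_prefixes_by_translation() -> set[str]:
    """Enumerate 4D codon families directly via biopython translation."""
    out = set()
    for b1 in "ACGT":
        for b2 in "ACGT":
            aas = {str(Seq(b1 + b2 + b3).translate()) for b3 in "ACGT"}
            if len(aas) == 1 and "*" not in aas:
                out.add(b1 + b2)
    return out


def recount_4d(sa: str, sb: str) -> tuple[list[int], int, int, int]:
    """Position-by-position 4D recount: (informative cols, n, ti, tv)."""
    families = fourfold_prefixes_by_translation()
    informative = []
    ti = tv = 0
    for i in range(0, len(sa), 3):
        ca, cb = sa[i:i + 3], sb[i:i + 3]
        pre = ca[:2]
        if pre != cb[:2] or pre not in families:
            continue
        x, y = ca[2], cb[2]
        if x not in "ACGT" or y not in "ACGT":
            continue
        informative.append(i + 2)
        if x != y:
            if {x, y} in ({"A", "G"}, {"C", "T"}):
                ti += 1
            else:
                tv += 1
    return informative, len(informative), ti, tv


def random_aligned_pair(rng: np.random.Generator, n_codons: int = 60):
    """A random pair of equally wide rows over {A,C,G,T,N,-}."""
    alphabet = np.array(list("ACGTN-"))
    probs = [0.22, 0.22, 0.22, 0.22, 0.06, 0.06]
    a = "".join(rng.choice(alphabet, size=3 * n_codons, p=probs))
    # second row: mostly equal to the first with random substitutions
    b = list(a)
    for i in range(len(b)):
        if rng.random() < 0.3:
            b[i] = str(rng.choice(alphabet, p=probs))
    return a, "".join(b)
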