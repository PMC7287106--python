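import numpy as np
import pytest

from isomirseq.align import AlignParams, HairpinAlignment
from isomirseq.reference import HairpinRecord, MatureAnnotation, ReferenceSet


@pytest.fixture
def toy_ref() -> ReferenceSet:
    """One hand-built hairpin with a known mature arm.

    hairpin: 60 nt; mature = positions [15, 37) (22 nt). The bases flanking
    the mature are chosen so templated extensions are unambiguous.
    """
    seq = "ACGTACGTACGTACC" + "TGAGGTAGTAGGTTGTATAGTT" + "GT" + "ACGTACGTACGTACGTACGTA"
    ref = ReferenceSet()
    ref.add(
        HairpinRecord("toy-mir-1", seq),
        [MatureAnnotation("toy-miR-1-5p", "toy-mir-1", 15, 37, "5p")],
    )
    return ref


@pytest.fixture
def toy_mature(toy_ref) -> str:
    return toy_ref.mature_sequence("toy-miR-1-5p")


def brute_force_best(read: str, ref: ReferenceSet, params: AlignParams):
    """Plain exhaustive decomposer: every (mature, offset5, body length) split.

    Written independently of the production aligner as the minimal-score
    oracle: enumerate, filter by the admissibility bounds, pick the smallest
    (n_subst, tail_len, |off5|+|off3|, |off5|, mature_id, off5, off3) key.
    Returns (mature_id, offset5, offset3, tail, n_subst) or None.
    """
    candidates = []
    for m in ref.matures:
        hp = ref.hairpins[m.hairpin_id].sequence
        for offset5 in range(-params.max_shift5, params.max_shift5 + 1):
            start = m.start + offset5
            if start < 0:
                continue
            for body_len in range(1, len(read) + 1):
                tail = read[body_len:]
                if len(tail) > params.max_tail:
                    continue
                if start + body_len > len(hp):
                    continue
                offset3 = start + body_len - m.end
                if abs(offset3) > params.max_shift3:
                    continue
                n_subst = sum(
                    1 for i in range(body_len) if read[i] != hp[start + i]
                )
                if n_subst > params.max_mismatch:
                    continue
                key = (
                    n_subst,
                    len(tail),
                    abs(offset5) + abs(offset3),
                    abs(offset5),
                    m.mature_id,
                    offset5,
                    offset3,
                )
                candidates.append((key, (m.mature_id, offset5, offset3, tail, n_subst)))
    if not candidates:
        return None
    return min(candidates)[1]


def alignment_tuple(aln: HairpinAlignment):
    return (aln.mature_id, aln.offset5, aln.offset3, aln.nta_tail, aln.n_subst)


def mutate_read(rng: np.random.Generator, seq: str) -> str:
    """Random end shifts / tails / substitutions applied to a mature sequence."""
    bases = "ACGT"
    s = seq
    op = rng.integers(0, 5)
    if op == 0:  # 3' trim
        s = s[: len(s) - int(rng.integers(1, 4))]
    elif op == 1:  # random 3' extension
        s = s + "".join(rng.choice(list(bases), size=int(rng.integers(1, 4))))
    elif op == 2:  # 5' trim
        s = s[int(rng.integers(1, 3)) :]
    elif op == 3:  # substitution
        i = int(rng.integers(0, len(s)))
        s = s[:i] + str(rng.choice([b for b in bases if b != s[i]])) + s[i + 1 :]
    return s
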