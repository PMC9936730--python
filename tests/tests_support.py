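"""Small shared helpers for the test suite."""

from karyofish.collinearity import CENTROMERE, Permutation


def make_permutation(markers, token_at, ref_slot):
    """Wrap a raw marker order (dense indices) into a Permutation with the
    centromere token inserted at ``token_at``."""
    seq = list(markers)
    seq.insert(token_at, CENTROMERE)
    n = len(markers)
    return Permutation(
        chrom_id="synthetic", group=1, sequence=tuple(seq),
        ref_slot=ref_slot,
        dense_to_probe=tuple(f"p{i}" for i in range(n)),
        boundary_to_ref=tuple(range(n + 1)))
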