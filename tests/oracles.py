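"""Independent brute-force oracles shared by the unit and acceptance suites."""

from __future__ import annotations

from ibdmap.variantstore import HET, HOM_ALT, HOM_REF, MISSING


def roh_oracle(positions, states, params):
    """Exhaustive-window ROH finder: enumerate every start/end pair.

    Windows over the non-missing calls must start and end homozygous and
    contain at most ``max_het`` heterozygous calls; containment-maximal
    windows passing the min-variant and min-length rules are reported as
    (start position, end position, homozygous-call count) tuples.
    """
    pos = [p for p, s in zip(positions, states) if s != MISSING]
    st_ = [s for s in states if s != MISSING]
    n = len(st_)
    feasible = []
    for i in range(n):
        for j in range(i, n):
            win = st_[i : j + 1]
            if win[0] == HET or win[-1] == HET:
                continue
            if sum(s == HET for s in win) > params.max_het:
                continue
            feasible.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in feasible
        if not any((a <= i and j <= b and (a, b) != (i, j)) for (a, b) in feasible)
    ]
    out = []
    for i, j in maximal:
        n_hom = sum(s in (HOM_REF, HOM_ALT) for s in st_[i : j + 1])
        span = pos[j] - pos[i]
        if n_hom >= params.min_variants and span >= params.min_length_bp:
            out.append((pos[i], pos[j], n_hom))
    return sorted(out)
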