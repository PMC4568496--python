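"""Independent brute-force oracles.

Everything here is deliberately naive (character-by-character sliding
windows, exhaustive nested loops, an explicit codon table) and shares no
code with the package's scanners, so agreement between the two routes is
meaningful.
"""

from __future__ import annotations

from typing import Optional

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def arm_matches(genome: str, ebe: str, max_mm: int) -> set[tuple[int, str, int]]:
    """All (start, strand, mismatches) windows matching the single-arm rule:
    T aligned to EBE position 0 on the match strand, <= max_mm mismatches
    over positions 1..L-1."""
    L = len(ebe)
    out = set()
    for i in range(len(genome) - L + 1):
        w = genome[i : i + L]
        if w[0] == "T":
            mm = sum(a != b for a, b in zip(w[1:], ebe[1:]))
            if mm <= max_mm:
                out.add((i, "+", mm))
        rcw = revcomp(w)
        if rcw[0] == "T":
            mm = sum(a != b for a, b in zip(rcw[1:], ebe[1:]))
            if mm <= max_mm:
                out.add((i, "-", mm))
    return out


def paired_hits(
    genome: str,
    left_ebe: str,
    right_ebe: str,
    min_mm: int,
    max_mm: int,
    min_spacer: int,
    max_spacer: int,
    arrangements: tuple[str, ...],
) -> set[tuple]:
    """Exhaustive paired scan. Keys: (up_start, up_end, down_start, down_end,
    arrangement, spacer, mm_up, mm_down)."""
    ebes = {"L": left_ebe, "R": right_ebe}
    hits = set()
    for arr in arrangements:
        up_ebe, down_ebe = ebes[arr[0]], ebes[arr[1]]
        ups = [m for m in arm_matches(genome, up_ebe, max_mm) if m[1] == "+"]
        downs = [m for m in arm_matches(genome, down_ebe, max_mm) if m[1] == "-"]
        for i, _, m1 in ups:
            up_end = i + len(up_ebe)
            for j, _, m2 in downs:
                spacer = j - up_end
                if not (min_spacer <= spacer <= max_spacer):
                    continue
                total = m1 + m2
                if not (min_mm <= total <= max_mm):
                    continue
                hits.add((i, up_end, j, j + len(down_ebe), arr, spacer, m1, m2))
    return hits


def design_pairs(
    region: str, ebe_min: int, ebe_max: int, spacer_min: int, spacer_max: int
) -> set[tuple[int, int, int, int]]:
    """Exhaustive enumeration over (start, len_left, spacer, len_right)."""
    n = len(region)
    out = set()
    for s in range(n):
        if region[s] != "T":
            continue
        for len_l in range(ebe_min, ebe_max + 1):
            for spacer in range(spacer_min, spacer_max + 1):
                for len_r in range(ebe_min, ebe_max + 1):
                    e1 = s + len_l
                    t = e1 + spacer
                    e2 = t + len_r
                    if e2 > n:
                        continue
                    if region[e2 - 1] != "A":
                        continue
                    if "N" in region[s:e1] or "N" in region[t:e2]:
                        continue
                    out.add((s, len_l, spacer, len_r))
    return out


def motif_hits(seq: str, pattern: str, both_strands: bool) -> set[tuple[int, str]]:
    """Sliding-window IUPAC match at every offset and strand."""
    from talenscan.seqio import iupac_matches

    m = len(pattern)
    out = set()
    for i in range(len(seq) - m + 1):
        w = seq[i : i + m]
        if all(iupac_matches(pattern[j], w[j]) for j in range(m)):
            out.add((i, "+"))
        if both_strands:
            rcw = revcomp(w)
            if all(iupac_matches(pattern[j], rcw[j]) for j in range(m)):
                out.add((i, "-"))
    return out


def pcr_product(template: str, fwd: str, rev: str, max_len: int) -> Optional[int]:
    """Shortest exact-primer product length over all site pairs."""
    site = revcomp(rev)
    products = []
    for f in range(len(template) - len(fwd) + 1):
        if template[f : f + len(fwd)] != fwd:
            continue
        for r in range(len(template) - len(site) + 1):
            if template[r : r + len(site)] != site:
                continue
            if r < f + len(fwd):
                continue
            length = r + len(site) - f
            if length <= max_len:
                products.append(length)
    return min(products) if products else None


# standard genetic code, codons enumerated in TCAG order
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: aa
    for (a, b, c), aa in zip(
        ((a, b, c) for a in "TCAG" for b in "TCAG" for c in "TCAG"), _AAS
    )
}


def translate_to_stop(seq: str) -> str:
    """Translate whole codons until the first stop (exclusive)."""
    protein = []
    for i in range(0, len(seq) - 2, 3):
        aa = CODON_TABLE[seq[i : i + 3]]
        if aa == "*":
            break
        protein.append(aa)
    return "".join(protein)


def wilson_interval(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """Textbook Wilson score interval (z defaults to the 97.5% normal point)."""
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = (z / denom) * ((p * (1 - p) / n + z**2 / (4 * n**2)) ** 0.5)
    return center - half, center + half
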