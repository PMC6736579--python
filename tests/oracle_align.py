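"""Independent brute-force local-alignment oracle (pure Python).

Implements the same published canonical alignment rule as the package's
aligner — affine gaps costing gap_open + L*gap_extend, IUPAC-set-intersection
matching, co-optimal ties resolved by smallest (query_start, subject_start,
query_end, subject_end), move preference diagonal > gap-in-subject >
gap-in-query, open preferred over extend, stop preferred at score 0 — but
shares no code with it: plain nested-list dynamic programming, no numpy in
the fill, written directly from the rule.
"""

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"}, "U": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

NEG = -(10 ** 15)


def brute_force_local(query, subject, match=2, mismatch=-3, gap_open=-5,
                      gap_extend=-2):
    """Return dict(score, identity, query_coverage, q_span, s_span, columns)."""
    q, s = query.upper(), subject.upper()
    m, n = len(q), len(s)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    pH = [[0] * (n + 1) for _ in range(m + 1)]
    pE = [[0] * (n + 1) for _ in range(m + 1)]
    pF = [[0] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e_open = H[i - 1][j] + gap_open + gap_extend
            e_ext = E[i - 1][j] + gap_extend
            if e_open >= e_ext:
                E[i][j], pE[i][j] = e_open, 0
            else:
                E[i][j], pE[i][j] = e_ext, 1
            f_open = H[i][j - 1] + gap_open + gap_extend
            f_ext = F[i][j - 1] + gap_extend
            if f_open >= f_ext:
                F[i][j], pF[i][j] = f_open, 0
            else:
                F[i][j], pF[i][j] = f_ext, 1
            hit = bool(IUPAC[qi] & IUPAC[s[j - 1]])
            v = H[i - 1][j - 1] + (match if hit else mismatch)
            p = 1
            if E[i][j] > v:
                v, p = E[i][j], 2
            if F[i][j] > v:
                v, p = F[i][j], 3
            if v <= 0:
                v, p = 0, 0
            H[i][j], pH[i][j] = v, p
            if v > best:
                best = v
    if best == 0:
        return {"score": 0, "identity": 0.0, "query_coverage": 0.0,
                "q_span": (0, 0), "s_span": (0, 0), "columns": []}

    chosen = None
    for ei in range(1, m + 1):
        for ej in range(1, n + 1):
            if H[ei][ej] != best:
                continue
            i, j, cols, state = ei, ej, [], "H"
            while True:
                if state == "H":
                    p = pH[i][j]
                    if p == 0:
                        break
                    if p == 1:
                        cols.append((i - 1, j - 1))
                        i, j = i - 1, j - 1
                    elif p == 2:
                        state = "E"
                    else:
                        state = "F"
                elif state == "E":
                    cols.append((i - 1, -1))
                    if pE[i][j] == 0:
                        state = "H"
                    i -= 1
                else:
                    cols.append((-1, j - 1))
                    if pF[i][j] == 0:
                        state = "H"
                    j -= 1
            cols.reverse()
            key = (i, j, ei, ej)
            if chosen is None or key < chosen[0]:
                chosen = (key, i, j, ei, ej, cols)
    _, qs, ss, qe, se, cols = chosen
    matches = sum(
        1 for ci, cj in cols
        if ci >= 0 and cj >= 0 and (IUPAC[q[ci]] & IUPAC[s[cj]])
    )
    return {
        "score": best,
        "identity": 100.0 * matches / len(cols),
        "query_coverage": 100.0 * (qe - qs) / m,
        "q_span": (qs, qe),
        "s_span": (ss, se),
        "columns": cols,
    }
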