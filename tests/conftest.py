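"""Shared fixtures: a tiny enzyme catalog, a 3-genus/6-species reference set,
and independent oracles used across modules."""

import numpy as np
import pytest

from metasig.simulate import (CohortDesign, default_species_layout,
                              generate_reference_set, synthetic_catalog)


@pytest.fixture(scope="session")
def small_catalog():
    return synthetic_catalog(n_enzymes=6, length_range=(150, 200), seed=101)


@pytest.fixture(scope="session")
def species_layout():
    return default_species_layout(6, 3)


@pytest.fixture(scope="session")
def reference_set(small_catalog, species_layout):
    entry_ids = [e.entry_id for e in small_catalog]
    planted = {s: [entry_ids[i % len(entry_ids)]]
               for i, s in enumerate(sorted(species_layout))}
    return generate_reference_set(small_catalog, species_layout, planted,
                                  genome_length=8000, identity_band=(85, 100),
                                  seed=202)


@pytest.fixture(scope="session")
def small_design(species_layout):
    return CohortDesign(species=sorted(species_layout), n_control=4, n_case=4,
                        depth=400, n_contigs=50, read_length=100,
                        contig_length_range=(400, 900), seed=7)


# ---------------------------------------------------------------------------
# independent oracles


def sw_align_oracle(query, subject, matrix, gap_open=11.0, gap_extend=1.0):
    """Quadratic Smith-Waterman with affine gaps (gap of length L costs
    gap_open + L * gap_extend) and full traceback.

    Returns (score, identity_pct, coverage_pct_of_subject). Independent of
    the package's aligner: plain dynamic programming over three state
    matrices with explicit traceback pointers.
    """
    n, m = len(query), len(subject)
    NEG = -1e18
    M = np.full((n + 1, m + 1), 0.0)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in subject (consumes query)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in query (consumes subject)
    ptr = {}
    best, best_cell = 0.0, None
    go, ge = gap_open + gap_extend, gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[query[i - 1], subject[j - 1]]
            opts = [(0.0, "0"), (M[i - 1, j - 1], "M"),
                    (Ix[i - 1, j - 1], "X"), (Iy[i - 1, j - 1], "Y")]
            val, src = max(opts, key=lambda t: t[0])
            M[i, j] = val + s
            ptr[("M", i, j)] = src
            ix_opts = [(M[i - 1, j] - go, "M"), (Ix[i - 1, j] - ge, "X")]
            Ix[i, j], src = max(ix_opts, key=lambda t: t[0])[0], \
                max(ix_opts, key=lambda t: t[0])[1]
            ptr[("X", i, j)] = src
            iy_opts = [(M[i, j - 1] - go, "M"), (Iy[i, j - 1] - ge, "Y")]
            Iy[i, j], src = max(iy_opts, key=lambda t: t[0])[0], \
                max(iy_opts, key=lambda t: t[0])[1]
            ptr[("Y", i, j)] = src
            if M[i, j] > best:
                best, best_cell = M[i, j], (i, j)
    if best_cell is None:
        return 0.0, 0.0, 0.0
    i, j = best_cell
    state = "M"
    matches = columns = 0
    j_end = j
    while True:
        src = ptr[(state, i, j)]
        if state == "M":
            columns += 1
            if query[i - 1] == subject[j - 1]:
                matches += 1
            i, j = i - 1, j - 1
        elif state == "X":
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
        if src == "0":
            break
        state = src
    identity = 100.0 * matches / columns
    coverage = 100.0 * (j_end - j) / m
    return best, identity, coverage


def orf_scan_oracle(sequence, min_nt_length):
    """Naive six-frame ORF scan: per frame, walk codons, track the first ATG
    after the previous stop, emit (start, end, strand) in forward coordinates.
    """
    from metasig.seqio import revcomp
    stops = {"TAA", "TAG", "TGA"}
    out = []
    L = len(sequence)
    for strand, s in (("+", sequence.upper()), ("-", revcomp(sequence.upper()))):
        for frame in range(3):
            start = None
            pos = frame
            while pos + 3 <= L:
                codon = s[pos:pos + 3]
                if any(c not in "ACGT" for c in codon):
                    start = None
                elif codon in stops:
                    if start is not None and pos + 3 - start >= min_nt_length:
                        a, b = start, pos + 3
                        if strand == "-":
                            a, b = L - b, L - a
                        out.append((a, b, strand))
                    start = None
                elif codon == "ATG" and start is None:
                    start = pos
                pos += 3
    return sorted(out)


def bh_oracle(p):
    """Step-up BH by the textbook definition: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        q_sorted[i] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def tmm_oracle(counts_df, logratio_trim=0.3, abs_trim=0.05):
    """Scalar-loop reimplementation of the published TMM formula.

    Kept deliberately different in style from the package version: per-sample
    python loops over features, explicit sorting instead of rank masks.
    """
    import math
    cols = list(counts_df.columns)
    lib = {c: float(counts_df[c].sum()) for c in cols}
    uq = {c: float(np.quantile(counts_df[c].to_numpy(float), 0.75)) / lib[c]
          for c in cols}
    mean_uq = sum(uq.values()) / len(cols)
    ref = min(cols, key=lambda c: abs(uq[c] - mean_uq))
    logf = {}
    for c in cols:
        if c == ref:
            logf[c] = 0.0
            continue
        rows = [(float(a), float(b)) for a, b in
                zip(counts_df[c], counts_df[ref]) if a > 0 and b > 0]
        n = len(rows)
        stats = []
        for yk, yr in rows:
            m_ = math.log2((yk / lib[c]) / (yr / lib[ref]))
            a_ = 0.5 * math.log2((yk / lib[c]) * (yr / lib[ref]))
            v_ = (lib[c] - yk) / (lib[c] * yk) + (lib[ref] - yr) / (lib[ref] * yr)
            stats.append((m_, a_, v_))
        lo_m = int(np.floor(n * logratio_trim)) + 1
        lo_a = int(np.floor(n * abs_trim)) + 1
        def avg_rank(values):
            order = sorted(range(len(values)), key=lambda i: values[i])
            ranks = [0.0] * len(values)
            i = 0
            while i < len(order):
                j = i
                while j + 1 < len(order) and \
                        values[order[j + 1]] == values[order[i]]:
                    j += 1
                mean_rank = (i + j) / 2.0 + 1.0
                for t in range(i, j + 1):
                    ranks[order[t]] = mean_rank
                i = j + 1
            return ranks

        m_rank_list = avg_rank([t[0] for t in stats])
        a_rank_list = avg_rank([t[1] for t in stats])
        m_rank = {id(t): m_rank_list[i] for i, t in enumerate(stats)}
        a_rank = {id(t): a_rank_list[i] for i, t in enumerate(stats)}
        num = den = 0.0
        for t in stats:
            if lo_m <= m_rank[id(t)] <= n + 1 - lo_m and \
                    lo_a <= a_rank[id(t)] <= n + 1 - lo_a:
                num += t[0] / t[2]
                den += 1.0 / t[2]
        logf[c] = num / den
    mean_logf = sum(logf.values()) / len(cols)
    return {c: 2.0 ** (v - mean_logf) for c, v in logf.items()}
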