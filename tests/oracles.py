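"""Independent brute-force oracles, coded separately from the library paths
they check (scalar loops, textbook formulas)."""

import numpy as np


def wc84_components_scalar(counts_by_pop):
    """Weir & Cockerham (1984) variance components for one biallelic SNP.

    counts_by_pop : list of (n_AA, n_Aa, n_aa) genotype counts per population
    Returns (a, b, c) computed with plain scalar arithmetic.
    """
    r = len(counts_by_pop)
    n = [sum(t) for t in counts_by_pop]
    p = [(2 * t[0] + t[1]) / (2 * ni) for t, ni in zip(counts_by_pop, n)]
    h = [t[1] / ni for t, ni in zip(counts_by_pop, n)]
    nbar = sum(n) / r
    nc = (sum(n) - sum(ni**2 for ni in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / sum(n)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / sum(n)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - ((r - 1) / r) * s2
        - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def pi_pairwise_scalar(haplotypes, length):
    """Nucleotide diversity by explicit pairwise haplotype comparison."""
    n = len(haplotypes)
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum(haplotypes[i] != haplotypes[j]))
            pairs += 1
    return total / pairs / length


def watterson_theta_scalar(haplotypes, length):
    n = len(haplotypes)
    seg = 0
    for s in range(haplotypes.shape[1]):
        col = haplotypes[:, s]
        if col.min() != col.max():
            seg += 1
    a_n = sum(1.0 / i for i in range(1, n))
    return seg / a_n / length


def hwe_chi2_scalar(n_AA, n_Aa, n_aa):
    """Textbook Hardy-Weinberg chi-square, coded independently."""
    n = n_AA + n_Aa + n_aa
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1 - p
    exp = [n * p * p, 2 * n * p * q, n * q * q]
    obs = [n_AA, n_Aa, n_aa]
    return sum((o - e) ** 2 / e for o, e in zip(obs, exp) if e > 0)


def rda_two_step_scalar(Y, X):
    """RDA by explicit normal-equations regression then eigen-decomposition,
    a second path to the constrained axes.

    Returns (eigenvalues, fitted values) for centred Y and standardised X.
    """
    Yc = Y - Y.mean(axis=0)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    B = np.linalg.solve(Xs.T @ Xs, Xs.T @ Yc)
    Yhat = Xs @ B
    n = Y.shape[0]
    C = Yhat.T @ Yhat / (n - 1)
    eig = np.sort(np.linalg.eigvalsh(C))[::-1]
    return eig[eig > 1e-12], Yhat


def random_genotype_table(rng, max_pops=4, max_n=12):
    """Random per-population genotype counts with at least 2 diploids each
    and a polymorphic pooled sample."""
    while True:
        r = rng.integers(2, max_pops + 1)
        counts = []
        for _ in range(r):
            n = rng.integers(2, max_n + 1)
            alleles = rng.random()
            gts = rng.multinomial(
                n, [(1 - alleles) ** 2, 2 * alleles * (1 - alleles), alleles**2]
            )
            counts.append(tuple(int(x) for x in gts))
        ps = [(2 * t[0] + t[1]) / (2 * sum(t)) for t in counts]
        if 0 < np.mean(ps) < 1 and (max(ps) > 0 or min(ps) < 1):
            pooled_p = sum(2 * t[0] + t[1] for t in counts) / sum(
                2 * sum(t) for t in counts
            )
            if 0 < pooled_p < 1:
                return counts


def counts_to_dosages(counts_by_pop):
    """Expand genotype counts to a dosage matrix + group index lists."""
    cols = []
    groups = []
    start = 0
    for n_AA, n_Aa, n_aa in counts_by_pop:
        block = [2.0] * n_AA + [1.0] * n_Aa + [0.0] * n_aa
        cols.extend(block)
        groups.append(np.arange(start, start + len(block)))
        start += len(block)
    return np.array(cols)[:, None], groups
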