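"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive (dictionaries, nested loops, full
DP matrices, direct summation) and shares no code with the package.
"""

from __future__ import annotations

import math

# Hand-typed standard genetic code (independent of Biopython).
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_oracle(nt: str) -> str | None:
    if len(nt) % 3 != 0:
        return None
    aa = "".join(CODON_TABLE[nt[i : i + 3]] for i in range(0, len(nt), 3))
    return None if "*" in aa else aa


def groupby_oracle(rows):
    """rows of (sample_id, junction_nt, count) -> {(sample, nt): total}."""
    agg: dict[tuple[str, str], int] = {}
    for sample_id, nt, count in rows:
        agg[(sample_id, nt)] = agg.get((sample_id, nt), 0) + count
    return agg


def levenshtein_matrix_oracle(a: str, b: str) -> int:
    """Full (len+1)x(len+1) DP matrix, no optimisation."""
    m, n = len(a), len(b)
    d = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        d[i][0] = i
    for j in range(n + 1):
        d[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d[i][j] = min(
                d[i - 1][j] + 1,
                d[i][j - 1] + 1,
                d[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
    return d[m][n]


def morisita_horn_oracle(x: dict, y: dict) -> float:
    keys = set(x) | set(y)
    X = sum(x.values())
    Y = sum(y.values())
    num = 2 * sum(x.get(k, 0) * y.get(k, 0) for k in keys)
    den = (
        sum(v * v for v in x.values()) / X**2
        + sum(v * v for v in y.values()) / Y**2
    ) * X * Y
    return num / den


def weighted_jaccard_oracle(x: dict, y: dict) -> float:
    keys = set(x) | set(y)
    num = sum(min(x.get(k, 0.0), y.get(k, 0.0)) for k in keys)
    den = sum(max(x.get(k, 0.0), y.get(k, 0.0)) for k in keys)
    return num / den


def publicness_oracle(subject_aas: dict[str, set[str]], groups: dict[str, str]):
    """Exhaustive presence tally: {aa: label} over per-subject AA sets."""
    labels = {}
    universe = set().union(*subject_aas.values())
    for aa in universe:
        carriers = [s for s, aas in subject_aas.items() if aa in aas]
        gs = {groups[s] for s in carriers}
        if len(carriers) == 1:
            labels[aa] = "private"
        elif gs == {"control", "case"}:
            labels[aa] = "public_inclusive"
        elif gs == {"control"}:
            labels[aa] = "public_exclusive_control"
        else:
            labels[aa] = "public_exclusive_case"
    return labels


def cr_oracle(nt_aa_pairs) -> dict[str, int]:
    """{(nt, aa)} occurrences -> {aa: number of distinct nt}."""
    seen: dict[str, set[str]] = {}
    for nt, aa in nt_aa_pairs:
        seen.setdefault(aa, set()).add(nt)
    return {aa: len(nts) for aa, nts in seen.items()}


def neighborhood_oracle(focal: str, pool, d_max: int) -> int:
    return sum(
        1
        for s in set(pool)
        if s != focal and levenshtein_matrix_oracle(focal, s) <= d_max
    )


def pearson_oracle(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def ks_statistic_oracle(a, b) -> float:
    """sup |F_a - F_b| evaluated at every pooled point."""
    points = sorted(set(a) | set(b))
    best = 0.0
    for t in points:
        fa = sum(1 for v in a if v <= t) / len(a)
        fb = sum(1 for v in b if v <= t) / len(b)
        best = max(best, abs(fa - fb))
    return best


def gaussian_ols_loglik(y, X) -> float:
    """Closed-form maximised Gaussian log-likelihood of OLS via normal
    equations: ll = -n/2 (log(2 pi sigma2) + 1), sigma2 = RSS/n."""
    import numpy as np

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    sigma2 = float(resid @ resid) / n
    return -n / 2.0 * (math.log(2 * math.pi * sigma2) + 1.0)


def pair_assembly_oracle(rows):
    """rows of (cell_id, chain, aa) -> (pairs set, dropped counts)."""
    per_cell: dict[str, dict[str, set[str]]] = {}
    for cell, chain, aa in set(rows):
        per_cell.setdefault(cell, {"alpha": set(), "beta": set()})[chain].add(aa)
    pairs = set()
    dropped = {"multichain": 0, "incomplete": 0}
    for cell, chains in per_cell.items():
        if len(chains["alpha"]) > 1 or len(chains["beta"]) > 1:
            dropped["multichain"] += 1
        elif not chains["alpha"] or not chains["beta"]:
            dropped["incomplete"] += 1
        else:
            pairs.add((cell, next(iter(chains["alpha"])), next(iter(chains["beta"]))))
    return pairs, dropped
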