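"""Independent brute-force oracles used to validate the engine.

These deliberately avoid the package's vectorised kernels: the mating
oracle enumerates all ordered parental crosses, the one-locus oracle is a
scalar two-sex recursion, and the partial-correlation oracle inverts the
rank correlation matrix.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from resistsim.genotypes import GENOTYPES, HAPLOTYPES, LOCUS_GENOTYPES


def _parent_gametes(genotype, r: float) -> dict[str, float]:
    """Mendelian gamete distribution of one parent, built from first
    principles on the chromosome pair rather than the package's table."""
    # chromosomes as (allele1, allele2) pairs
    def chromosomes(g):
        l1, l2 = g.locus1, g.locus2
        if g.phase == "coupling":
            return ("R", "R"), ("S", "S")
        if g.phase == "repulsion":
            return ("R", "S"), ("S", "R")
        a = ("S", "R") if l1 == "RS" else (l1[0], l1[0])
        b = ("S", "R") if l2 == "RS" else (l2[0], l2[0])
        # assign alleles to the two chromosomes; for single heterozygotes
        # the phase is immaterial
        return (a[0], b[0]), (a[1], b[1])

    c1, c2 = chromosomes(genotype)
    out = {h: 0.0 for h in HAPLOTYPES}
    # parental (no crossover) with prob (1-r), recombinant with prob r
    for (x, y), p in (
        ((c1[0], c1[1]), (1 - r) / 2),
        ((c2[0], c2[1]), (1 - r) / 2),
        ((c1[0], c2[1]), r / 2),
        ((c2[0], c1[1]), r / 2),
    ):
        out[x + y] += p
    return out


def _offspring_genotype(hap_f: str, hap_m: str):
    def locus(a, b):
        n = (a == "R") + (b == "R")
        return LOCUS_GENOTYPES[n]

    l1 = locus(hap_f[0], hap_m[0])
    l2 = locus(hap_f[1], hap_m[1])
    if l1 == "RS" and l2 == "RS":
        phase = "coupling" if {hap_f, hap_m} == {"SS", "RR"} else "repulsion"
    else:
        phase = "na"
    return l1, l2, phase


def brute_force_offspring(freq: np.ndarray, w: np.ndarray, r: float) -> np.ndarray:
    """Offspring genotype distribution by enumerating all 10 x 10 ordered
    (mother, father) crosses weighted by fitness-scaled frequencies, each
    cross contributing its Mendelian offspring distribution."""
    mother_p = freq[0] * w[0]
    mother_p = mother_p / mother_p.sum()
    father_p = freq[1] * w[1]
    father_p = father_p / father_p.sum()
    index = {
        (g.locus1, g.locus2, g.phase): k for k, g in enumerate(GENOTYPES)
    }
    out = np.zeros(10)
    for gi, gmother in enumerate(GENOTYPES):
        gam_f = _parent_gametes(gmother, r)
        for gj, gfather in enumerate(GENOTYPES):
            weight = mother_p[gi] * father_p[gj]
            if weight == 0.0:
                continue
            gam_m = _parent_gametes(gfather, r)
            for hf, pf in gam_f.items():
                for hm, pm in gam_m.items():
                    out[index[_offspring_genotype(hf, hm)]] += weight * pf * pm
    return out


def one_locus_next(q_f: float, q_m: float, w_f: np.ndarray, w_m: np.ndarray):
    """Scalar two-sex single-locus recursion: genotypes from the parental
    gamete pool, selection, gamete output per sex."""
    geno = np.array(
        [(1 - q_f) * (1 - q_m), q_f * (1 - q_m) + q_m * (1 - q_f), q_f * q_m]
    )
    def gamete_q(w):
        weighted = geno * w
        return (0.5 * weighted[1] + weighted[2]) / weighted.sum()

    return gamete_q(w_f), gamete_q(w_m)


def partial_rank_corr_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Partial correlation on ranks via inversion of the full rank
    correlation matrix: rho_xy.rest = -P_xy / sqrt(P_xx P_yy)."""
    ranks = np.column_stack(
        [stats.rankdata(X[:, j]) for j in range(X.shape[1])] + [stats.rankdata(y)]
    )
    corr = np.corrcoef(ranks, rowvar=False)
    prec = np.linalg.inv(corr)
    k = X.shape[1]
    out = np.empty(k)
    for j in range(k):
        out[j] = -prec[j, k] / np.sqrt(prec[j, j] * prec[k, k])
    return out
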