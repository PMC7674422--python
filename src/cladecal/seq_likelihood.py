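"""Strict-clock GTR+Γ nucleotide likelihood on a time tree.

Branch lengths in expected substitutions are ``clock_rate × duration`` with
durations in Myr; the rate matrix is scaled to one expected substitution per
unit branch length, so the clock rate is in substitutions per site per Myr.
Likelihoods use the pruning algorithm over compressed site patterns with
per-node rescaling; ``N`` and ``-`` are treated as missing data (a partial
vector of ones).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as gamma_dist

from ._errors import TaxonMappingError

__all__ = [
    "SubstModel",
    "Alignment",
    "TreeLikelihood",
    "felsenstein_loglik",
    "simulate_alignment",
    "jc69",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_MISSING = {"N", "-", "?"}


@dataclass(frozen=True)
class SubstModel:
    """General time-reversible model with discrete-Γ rate variation.

    ``exchangeabilities`` are the six upper-triangle GTR terms in the order
    AC, AG, AT, CG, CT, GT; ``gamma_shape=None`` disables rate variation.
    """

    exchangeabilities: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_frequencies: tuple = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = None
    n_categories: int = 4

    def __post_init__(self):
        ex = np.asarray(self.exchangeabilities, dtype=float)
        fr = np.asarray(self.base_frequencies, dtype=float)
        if ex.shape != (6,) or np.any(ex <= 0):
            raise ValueError("need 6 positive exchangeabilities")
        if fr.shape != (4,) or np.any(fr <= 0) or abs(fr.sum() - 1) > 1e-8:
            raise ValueError("base frequencies must be positive and sum to 1")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")

    def rate_matrix(self) -> np.ndarray:
        """Q scaled so the mean substitution rate at equilibrium is 1."""
        ex = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.base_frequencies, dtype=float)
        q = np.zeros((4, 4))
        iu = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for s, (i, j) in zip(ex, iu):
            q[i, j] = s * pi[j]
            q[j, i] = s * pi[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -np.dot(pi, np.diag(q))
        return q / scale

    def category_rates(self) -> np.ndarray:
        """Mean-of-bin discrete-Γ rates (mean 1 across categories)."""
        a = self.gamma_shape
        if a is None or not np.isfinite(a):
            return np.array([1.0])
        k = self.n_categories
        bounds = gamma_dist.ppf(np.arange(1, k) / k, a, scale=1.0 / a)
        # E[X; X <= c] for X ~ Gamma(a, 1/a) equals P(a+1, a c)
        upper = np.concatenate([gammainc(a + 1, a * bounds), [1.0]])
        lower = np.concatenate([[0.0], gammainc(a + 1, a * bounds)])
        return k * (upper - lower)

    def eigensystem(self):
        """(rates, eigvals, U, U_inv) for fast transition matrices.

        Uses the π-symmetrization of the reversible Q so the decomposition
        is real and orthogonal.
        """
        q = self.rate_matrix()
        pi = np.asarray(self.base_frequencies, dtype=float)
        sq = np.sqrt(pi)
        b = (q * sq[:, None]) / sq[None, :]
        w, v = np.linalg.eigh((b + b.T) / 2)
        u = v / sq[:, None]
        uinv = v.T * sq[None, :]
        return self.category_rates(), w, u, uinv


def jc69(gamma_shape=None, n_categories=4) -> SubstModel:
    """Jukes–Cantor special case of the GTR model."""
    return SubstModel(gamma_shape=gamma_shape, n_categories=n_categories)


@dataclass
class Alignment:
    """Equal-length nucleotide sequences with unique taxon names."""

    names: list
    sequences: list

    def __post_init__(self):
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate taxon names in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(self.sequences) != len(self.names):
            raise ValueError("names and sequences differ in number")
        if len(lengths) > 1:
            raise ValueError("sequences have unequal lengths")
        for nm, seq in zip(self.names, self.sequences):
            bad = set(seq.upper()) - set(_BASES) - _MISSING
            if bad:
                raise ValueError(
                    f"sequence {nm!r} contains unsupported characters {sorted(bad)}"
                )
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def codes(self) -> np.ndarray:
        """Integer matrix, 0..3 = ACGT, 4 = missing."""
        out = np.empty((len(self.names), self.n_sites), dtype=np.int8)
        for i, seq in enumerate(self.sequences):
            out[i] = [_CODE.get(c, 4) for c in seq]
        return out

    def patterns(self):
        """(unique site patterns as columns, counts)."""
        codes = self.codes()
        pats, counts = np.unique(codes, axis=1, return_counts=True)
        return pats, counts


class TreeLikelihood:
    """Pruning likelihood bound to one alignment/topology (MCMC hot path).

    Pattern compression and the model eigensystem are computed once; each
    call only rebuilds per-branch transition matrices for the given node
    ages and clock rate.
    """

    def __init__(self, alignment: Alignment, tree, model: SubstModel):
        order = []
        name_to_row = {nm: i for i, nm in enumerate(alignment.names)}
        for nm in tree.tip_names:
            if nm not in name_to_row:
                raise TaxonMappingError(f"tree tip {nm!r} missing from alignment")
            order.append(name_to_row[nm])
        self.tree = tree
        self.model = model
        pats, counts = alignment.patterns()
        self.patterns = pats[order]  # rows in tree tip order
        self.counts = counts
        self.rates, self.eigvals, self.u, self.uinv = model.eigensystem()
        self.pi = np.asarray(model.base_frequencies, dtype=float)
        # tip partials: identity rows, missing = all ones
        eye = np.vstack([np.eye(4), np.ones(4)])
        self.tip_partials = eye[self.patterns]  # (n_tips, n_patterns, 4)

    def _transition(self, length: float) -> np.ndarray:
        p = self.u @ (np.exp(self.eigvals * length)[:, None] * self.uinv)
        return np.clip(p, 0.0, None)

    def loglik_for_ages(self, ages: np.ndarray, clock_rate: float) -> float:
        if self.counts.size == 0:
            return 0.0
        tree = self.tree
        n_pat = self.patterns.shape[1]
        cat_logs = np.empty((len(self.rates), n_pat))
        for ci, rate in enumerate(self.rates):
            partial = {}
            log_scale = np.zeros(n_pat)
            for nd in tree.postorder:
                if nd < tree.n_tips:
                    partial[nd] = self.tip_partials[nd]
                    continue
                prod = None
                for child in tree.children[nd]:
                    bl = clock_rate * rate * (ages[nd] - ages[child])
                    p = self._transition(bl)
                    term = partial[child] @ p.T
                    prod = term if prod is None else prod * term
                    del partial[child]
                mx = prod.max(axis=1)
                mx = np.where(mx > 0, mx, 1.0)
                prod = prod / mx[:, None]
                log_scale += np.log(mx)
                partial[nd] = prod
            root_lik = partial[tree.root] @ self.pi
            with np.errstate(divide="ignore"):
                cat_logs[ci] = np.log(root_lik) + log_scale
        logs = logsumexp(cat_logs, axis=0) - np.log(len(self.rates))
        if np.any(~np.isfinite(logs)):
            return -np.inf
        return float(np.dot(self.counts, logs))


def felsenstein_loglik(alignment: Alignment, tree, clock_rate: float,
                       model: SubstModel) -> float:
    """Log likelihood of ``alignment`` on ``tree`` under a strict clock."""
    if clock_rate < 0:
        raise ValueError("clock_rate must be non-negative")
    return TreeLikelihood(alignment, tree, model).loglik_for_ages(
        tree.ages, clock_rate
    )


def simulate_alignment(tree, clock_rate: float, model: SubstModel,
                       n_sites: int, seed: int) -> Alignment:
    """Simulate sequences down the tree (sites iid given their Γ category)."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    rates = model.category_rates()
    cats = rng.integers(len(rates), size=n_sites)
    pi = np.asarray(model.base_frequencies, dtype=float)
    _, w, u, uinv = model.eigensystem()

    def transition(length):
        return np.clip(u @ (np.exp(w * length)[:, None] * uinv), 0.0, None)

    states = {tree.root: rng.choice(4, size=n_sites, p=pi)}
    # preorder: parents before children
    for nd in reversed(tree.postorder):
        if nd == tree.root:
            continue
        par = tree.parent[nd]
        duration = tree.ages[par] - tree.ages[nd]
        child_states = np.empty(n_sites, dtype=np.int64)
        for ci, rate in enumerate(rates):
            mask = cats == ci
            if not mask.any():
                continue
            p = transition(clock_rate * rate * duration)
            p = p / p.sum(axis=1, keepdims=True)
            src = states[par][mask]
            # vectorized categorical draw per source state
            r = rng.random(src.size)
            cum = np.cumsum(p, axis=1)
            child_states[mask] = (r[:, None] > cum[src]).sum(axis=1)
        states[nd] = child_states
    names, seqs = [], []
    for i, nm in enumerate(tree.tip_names):
        names.append(nm)
        seqs.append("".join(_BASES[s] for s in states[i]))
    return Alignment(names, seqs)


# ---------------------------------------------------------------------------
# FASTA I/O (wrapped and unwrapped dialects)
# ---------------------------------------------------------------------------


def read_fasta(path) -> Alignment:
    from Bio import SeqIO

    names, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq))
    return Alignment(names, seqs)


def write_fasta(alignment: Alignment, path, width: int = 70):
    with open(path, "w") as fh:
        for nm, seq in zip(alignment.names, alignment.sequences):
            fh.write(f">{nm}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")
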