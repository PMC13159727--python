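import numpy as np
import pytest

from stepstone.demography import DemeConfig, Demography, split
from stepstone.models import BEST_FIT_SE_NC_ADMIX, build_named_model


@pytest.fixture(scope="session")
def single_deme():
    """One deme, 4 haploid samples, Ne=10000, theta-per-site 0.4."""
    return Demography(demes=(DemeConfig("A", Ne=10_000.0, n_samples=2),), mu=1e-5)


@pytest.fixture(scope="session")
def two_deme_split():
    """Two demes splitting 5000 generations ago, no migration."""
    return Demography(
        demes=(DemeConfig("X", 2000.0, n_samples=3), DemeConfig("Y", 2000.0, n_samples=3)),
        events=(split(5000.0, "Y", "X"),),
        mu=1e-8,
    )


@pytest.fixture(scope="session")
def bestfit_demography():
    """The five-population admixed stepping-stone scenario, 5 diploids/pop."""
    samples = {k: 5 for k in ("SW", "SE", "C", "NC", "N")}
    return build_named_model("model4_SE_NC_admix", BEST_FIT_SE_NC_ADMIX, samples=samples)


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Brute-force Hardy-Weinberg exact test by direct enumeration of all
    heterozygote counts compatible with the allele totals (log-gamma
    arithmetic, independent of the package's recurrence implementation)."""
    from scipy.special import gammaln

    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    hets = np.arange(na % 2 if na <= nb else nb % 2, min(na, nb) + 1, 2)
    n_aa_all = (na - hets) // 2
    n_bb_all = n - n_aa_all - hets
    logp = (
        gammaln(n + 1)
        - gammaln(n_aa_all + 1)
        - gammaln(hets + 1)
        - gammaln(n_bb_all + 1)
        + hets * np.log(2.0)
        + gammaln(na + 1)
        + gammaln(nb + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_ab)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_cohort(n_ind, n_sites, seed, po_pairs=0):
    """Genotypes in Hardy-Weinberg equilibrium at uniform(0.1, 0.9) allele
    frequencies, with optional parent-offspring pairs appended by Mendelian
    transmission (returns genotypes, list of (parent, child) row pairs)."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, size=n_sites)
    G = (rng.random((n_ind, n_sites)) < p).astype(np.int8)
    G += (rng.random((n_ind, n_sites)) < p).astype(np.int8)
    pairs = []
    for k in range(po_pairs):
        parent, child = 2 * k, 2 * k + 1
        from_parent = np.where(
            G[parent] == 1, rng.integers(0, 2, n_sites).astype(np.int8), G[parent] // 2
        )
        from_mate = (rng.random(n_sites) < p).astype(np.int8)
        G[child] = from_parent + from_mate
        pairs.append((parent, child))
    return G, pairs
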