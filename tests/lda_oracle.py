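"""Exhaustive-enumeration oracle for the collapsed Gibbs LDA sampler.

For corpora of N tokens the posterior over topic assignments z in K^N is
enumerated exactly from the collapsed joint p(z, w), giving exact posterior
means of the document-topic proportions and of pairwise token co-assignment
probabilities. Independent of the sampler implementation.
"""

from itertools import product

import numpy as np
from scipy.special import gammaln


def enumerate_posterior(doc_ids, word_ids, K, V, D, alpha, eta):
    """Exact posterior summaries by enumerating all K^N assignment vectors.

    Returns (doc_topic_mean, coassignment) where doc_topic_mean[d, k] is
    E[(n_dk + alpha) / (n_d + K alpha)] and coassignment[i, j] is
    P(z_i == z_j), both under the collapsed posterior.
    """
    doc_ids = np.asarray(doc_ids)
    word_ids = np.asarray(word_ids)
    N = len(doc_ids)
    n_d = np.bincount(doc_ids, minlength=D).astype(float)

    log_weights = []
    thetas = []
    assignments = []
    for z in product(range(K), repeat=N):
        z = np.asarray(z)
        ndk = np.zeros((D, K))
        nkw = np.zeros((K, V))
        nk = np.zeros(K)
        np.add.at(ndk, (doc_ids, z), 1)
        np.add.at(nkw, (z, word_ids), 1)
        np.add.at(nk, z, 1)
        logw = (
            gammaln(ndk + alpha).sum()
            + gammaln(nkw + eta).sum()
            - gammaln(nk + V * eta).sum()
        )
        log_weights.append(logw)
        thetas.append((ndk + alpha) / (n_d[:, None] + K * alpha))
        assignments.append(z)
    log_weights = np.asarray(log_weights)
    w = np.exp(log_weights - log_weights.max())
    w /= w.sum()

    doc_topic = np.tensordot(w, np.asarray(thetas), axes=1)
    zmat = np.asarray(assignments)                       # (n_states, N)
    co = np.zeros((N, N))
    for i in range(N):
        co[i] = w @ (zmat == zmat[:, [i]])
    return doc_topic, co
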