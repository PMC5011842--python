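import numpy as np
import pytest
from hypothesis import settings

from stagemine.seminmf import LabelConstraints

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")


@pytest.fixture
def tiny_corpus_csv(tmp_path):
    """A small well-formed corpus file: 2 sites, 5 notes, 2 labeled."""
    path = tmp_path / "corpus.csv"
    path.write_text(
        "site_id,date,text,label\n"
        "alpha,2007-03-01,agency agreed to consider the program,1\n"
        "alpha,2007-04-15,planning call about readiness and budget,\n"
        "alpha,2007-06-02,first referral reviewed by the team,\n"
        "beta,2007-02-20,initial outreach letter sent,\n"
        "beta,2007-05-11,training schedule drafted with staff,2\n"
    )
    return path


@pytest.fixture
def tiny_descriptions_csv(tmp_path):
    path = tmp_path / "descriptions.csv"
    rows = ["stage_id,sentence"]
    sentences = {
        1: ["agreement to consider implementation", "initial contact and outreach"],
        2: ["planning and readiness review", "budget and feasibility assessment"],
        3: ["recruitment plan and referral review", "referral flow established"],
        4: ["training schedule set", "certification application submitted"],
    }
    for stage, sents in sentences.items():
        rows += [f"{stage},{s}" for s in sents]
    path.write_text("\n".join(rows) + "\n")
    return path


def random_problem(seed, L=60, K=25, S=4, labeled_rows=None, labeled_keywords=None):
    """Seeded random factorization problem with one-hot partial labels.

    Rows of X are normalized to sum to 1 like a document-term matrix; 10 %
    of rows and keywords are labeled by default.
    """
    rng = np.random.default_rng(seed)
    X = rng.random((L, K))
    X /= X.sum(axis=1, keepdims=True)
    if labeled_rows is None:
        labeled_rows = max(1, L // 10)
    if labeled_keywords is None:
        labeled_keywords = max(1, K // 10)
    F0 = np.zeros((L, S))
    for i in rng.choice(L, labeled_rows, replace=False):
        F0[i, rng.integers(S)] = 1.0
    G0 = np.zeros((K, S))
    for i in rng.choice(K, labeled_keywords, replace=False):
        G0[i, rng.integers(S)] = 1.0
    return X, LabelConstraints(F0=F0, G0=G0)
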