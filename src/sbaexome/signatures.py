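"""Mutational-signature analysis on 96 trinucleotide channels.

Somatic SNVs are tallied into the standard 96-channel catalogue (six
pyrimidine-centered substitutions C>A, C>G, C>T, T>A, T>C, T>G, each in 16
5'/3' flank contexts); signatures are extracted by multi-restart NMF with a
Kullback-Leibler objective, per-sample exposures are obtained by nonnegative
least-squares projection onto the signature weight matrix, and extracted
signatures are matched to a reference catalogue by symmetric mean KL
divergence [D(p||q) + D(q||p)] / 2.
"""

from __future__ import annotations

import warnings
from importlib import resources as importlib_resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.special import rel_entr
from sklearn.decomposition import NMF

from sbaexome.variants import VariantCall

SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
BASES = ["A", "C", "G", "T"]

#: fixed channel order: substitution-major, then 5' flank, then 3' flank
CHANNELS: list[str] = [
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
]
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def snv_channel(ref: str, alt: str, five: str, three: str) -> str | None:
    """Map an SNV with flanking bases to its pyrimidine-centered channel.

    Purine-reference SNVs are reverse-complemented so the mutated base is
    always C or T. Returns None for non-ACGT input.
    """
    if any(b not in "ACGT" for b in (ref, alt, five, three)):
        return None
    if ref in "AG":
        ref, alt = _revcomp(ref), _revcomp(alt)
        five, three = _revcomp(three), _revcomp(five)
    return f"{five}[{ref}>{alt}]{three}"


def build_catalog(
    calls_by_sample: Mapping[str, Sequence[VariantCall]],
    genome,
) -> tuple[pd.DataFrame, int]:
    """Build the samples x 96 mutation catalogue from somatic SNVs.

    ``genome`` must provide ``fetch(chrom, start, end)`` returning the
    reference sequence for a 1-based inclusive span (a mapping of chromosome
    name to sequence string also works). Non-SNV calls are ignored; SNVs
    whose flanks fall outside the contig or contain non-ACGT bases are
    skipped and counted. Returns (catalogue, n_skipped); row sums equal each
    sample's usable SNV count.
    """
    counts = np.zeros((len(calls_by_sample), 96), dtype=int)
    sample_ids = list(calls_by_sample)
    n_skipped = 0
    for row, sample in enumerate(sample_ids):
        for call in calls_by_sample[sample]:
            if call.variant_class != "SNV":
                continue
            try:
                if hasattr(genome, "fetch"):
                    context = str(genome.fetch(call.chrom, call.pos - 1, call.pos + 1)).upper()
                else:
                    seq = genome[call.chrom]
                    if call.pos < 2 or call.pos > len(seq) - 1:
                        raise IndexError
                    context = str(seq[call.pos - 2 : call.pos + 1]).upper()
            except (KeyError, IndexError, ValueError):
                n_skipped += 1
                continue
            if len(context) != 3:
                n_skipped += 1
                continue
            channel = snv_channel(call.ref, call.alt, context[0], context[2])
            if channel is None:
                n_skipped += 1
                continue
            counts[row, _CHANNEL_INDEX[channel]] += 1
    return pd.DataFrame(counts, index=sample_ids, columns=CHANNELS), n_skipped


def extract_signatures(
    catalog: pd.DataFrame,
    k: int,
    n_restarts: int = 50,
    seed: int = 0,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Extract ``k`` signatures by multi-restart KL-objective NMF.

    Runs ``n_restarts`` randomly initialized factorizations, keeps the one
    with the lowest reconstruction divergence, and normalizes each signature
    row to a probability vector over the 96 channels. Deterministic for a
    given seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(catalog.shape):
        raise ValueError(f"k={k} exceeds min(n_samples, 96) = {min(catalog.shape)}")
    x = catalog.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    best_err, best_h = np.inf, None
    for _ in range(n_restarts):
        model = NMF(
            n_components=k,
            init="random",
            solver="mu",
            beta_loss="kullback-leibler",
            max_iter=max_iter,
            tol=1e-6,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        with warnings.catch_warnings():
            # partial convergence of single restarts is expected; the
            # best-of-restarts selection is what matters
            warnings.simplefilter("ignore")
            model.fit(x)
        if model.reconstruction_err_ < best_err:
            best_err, best_h = model.reconstruction_err_, model.components_
    weights = best_h / best_h.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        weights, index=[f"S{i + 1}" for i in range(k)], columns=catalog.columns
    )


def project_exposures(catalog: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Project each sample's 96-vector onto the signature weight matrix.

    Per-sample nonnegative least squares; exposures are in mutation-count
    units (an exposure of 100 on a signature attributes ~100 of the sample's
    mutations to it).
    """
    w = weights.to_numpy(dtype=float)
    if np.any(w.sum(axis=1) == 0):
        raise ValueError("signature weight matrix contains an all-zero row")
    a = w.T  # 96 x k
    exposures = np.vstack([nnls(a, row)[0] for row in catalog.to_numpy(dtype=float)])
    return pd.DataFrame(exposures, index=catalog.index, columns=weights.index)


def symmetric_kl(p: Sequence[float], q: Sequence[float], epsilon: float = 1e-9) -> float:
    """Symmetric mean KL divergence [D(p||q) + D(q||p)] / 2, natural log.

    Both vectors are floored at ``epsilon`` and renormalized before the
    divergence is taken, so zero channels are well-defined.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("probability vectors must be nonnegative")
    p = np.maximum(p, epsilon)
    q = np.maximum(q, epsilon)
    p /= p.sum()
    q /= q.sum()
    return float((rel_entr(p, q).sum() + rel_entr(q, p).sum()) / 2.0)


def match_reference(
    weights: pd.DataFrame, reference: pd.DataFrame, epsilon: float = 1e-9
) -> dict[str, tuple[str, float]]:
    """Assign each extracted signature its nearest reference signature.

    Nearest by symmetric mean KL divergence; the assignment is independent
    per extracted signature (not forced bijective). Returns
    {extracted_name: (reference_name, divergence)}.
    """
    if reference.empty:
        raise ValueError("reference catalogue is empty")
    matches: dict[str, tuple[str, float]] = {}
    for name, row in weights.iterrows():
        divs = {
            ref_name: symmetric_kl(row.to_numpy(), ref_row.to_numpy(), epsilon)
            for ref_name, ref_row in reference.iterrows()
        }
        best = min(divs, key=divs.get)
        matches[str(name)] = (str(best), divs[best])
    return matches


def load_reference_catalog(path=None) -> pd.DataFrame:
    """Load a reference signature catalogue (signatures x 96 channels).

    Accepts any TSV whose columns follow the package channel order with a
    leading signature-name column. With no path, loads the bundled synthetic
    reference catalogue.
    """
    if path is None:
        path = importlib_resources.files("sbaexome.data").joinpath(
            "synthetic_reference_signatures.tsv"
        )
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != CHANNELS:
        raise ValueError("reference catalogue channel order does not match")
    return df


def rank_scan(
    catalog: pd.DataFrame,
    ks: Iterable[int],
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
) -> pd.DataFrame:
    """Advisory model-selection scan over candidate signature counts.

    For each k, reports the best reconstruction divergence and a stability
    score (mean best-pair cosine similarity of signatures across restarts);
    the choice of k remains the caller's.
    """
    rows = []
    rng = np.random.default_rng(seed)
    x = catalog.to_numpy(dtype=float)
    for k in ks:
        hs, errs = [], []
        for _ in range(n_restarts):
            model = NMF(
                n_components=k,
                init="random",
                solver="mu",
                beta_loss="kullback-leibler",
                max_iter=max_iter,
                tol=1e-6,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(x)
            h = model.components_
            h = h / np.maximum(h.sum(axis=1, keepdims=True), 1e-12)
            hs.append(h)
            errs.append(model.reconstruction_err_)
        best = hs[int(np.argmin(errs))]
        sims = []
        for h in hs:
            norm_b = best / np.linalg.norm(best, axis=1, keepdims=True)
            norm_h = h / np.linalg.norm(h, axis=1, keepdims=True)
            cos = norm_h @ norm_b.T
            sims.append(float(np.mean(cos.max(axis=1))))
        rows.append({"k": k, "reconstruction_err": float(min(errs)), "stability": float(np.mean(sims))})
    return pd.DataFrame(rows)
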