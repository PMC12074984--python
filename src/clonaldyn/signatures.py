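"""Mutational-signature attribution with fixed catalogues.

Signature extraction (hierarchical Dirichlet processes, deconvolution) is
upstream and out of scope; this module takes 96-channel trinucleotide-context
signature catalogues as given and implements the attribution arithmetic:
opportunity adjustment of a catalogue to a target genome's trinucleotide
frequencies, the per-mutation Bayesian signature-membership posterior,
branch-level attribution by summing per-mutation posteriors over the SNVs
assigned to a branch, and signature-specific burden-rate fits (delegating to
the burden mixed model).

Channels follow the canonical pyrimidine-centric COSMIC ordering: substitution
classes C>A, C>G, C>T, T>A, T>C, T>G, each over the sixteen 5'/3' flank
combinations in A, C, G, T order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .variant_filters import fit_burden_rate

__all__ = [
    "CHANNELS", "CONTEXTS_32", "channel_context", "synthetic_catalog",
    "adjust_for_opportunities", "mutation_posterior", "branch_attribution",
    "signature_burden_rate",
]

_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

CHANNELS = tuple(f"{five}[{sub}]{three}"
                 for sub in _SUBS for five in _BASES for three in _BASES)

CONTEXTS_32 = tuple(f"{five}{ref}{three}"
                    for ref in "CT" for five in _BASES for three in _BASES)


def channel_context(channel: str) -> str:
    """Trinucleotide context of a channel, e.g. 'A[C>T]G' -> 'ACG'."""
    return channel[0] + channel[2] + channel[-1]


def synthetic_catalog() -> pd.DataFrame:
    """Stylized stand-in catalogue for SBS1/SBS5/SBS18-like processes.

    Synthetic profiles built in code, not the reference catalogue: 'SBS1'
    concentrates C>T mass at NCG contexts (CpG deamination), 'SBS5' is a
    broad, nearly flat profile (clock-like damage/repair), and 'SBS18' is
    dominated by C>A (oxidative damage).  Each column sums to one.  Suitable
    for tests and worked examples; substitute measured catalogues for real
    analyses.
    """
    idx = pd.Index(CHANNELS, name="channel")
    cat = pd.DataFrame(0.0, index=idx, columns=["SBS1", "SBS5", "SBS18"])
    for ch in CHANNELS:
        sub = ch[2:5]
        cpg = ch[-1] == "G" and sub.startswith("C")
        if sub == "C>T":
            cat.loc[ch, "SBS1"] = 10.0 if cpg else 0.3
        cat.loc[ch, "SBS5"] = 1.0 + 0.5 * (sub in ("C>T", "T>C"))
        if sub == "C>A":
            cat.loc[ch, "SBS18"] = 5.0
        else:
            cat.loc[ch, "SBS18"] = 0.1
    return cat / cat.sum(axis=0)


def adjust_for_opportunities(catalog: pd.DataFrame,
                             reference_freqs: pd.Series,
                             target_freqs: pd.Series) -> pd.DataFrame:
    """Rescale a catalogue to a target genome's trinucleotide opportunities.

    Each channel's probability is multiplied by the ratio of the target to
    the reference frequency of its trinucleotide context (32 pyrimidine-
    centric contexts) and the column renormalized to one.
    """
    ref = reference_freqs.reindex(CONTEXTS_32)
    tgt = target_freqs.reindex(CONTEXTS_32)
    if ref.isna().any() or tgt.isna().any():
        missing = set(CONTEXTS_32) - set(reference_freqs.index) | \
            set(CONTEXTS_32) - set(target_freqs.index)
        raise ValueError(f"missing trinucleotide contexts: {sorted(missing)}")
    if (ref <= 0).any():
        raise ValueError("reference trinucleotide frequencies must be positive")
    ratio = (tgt / ref)
    factors = pd.Series([ratio[channel_context(ch)] for ch in catalog.index],
                        index=catalog.index)
    adjusted = catalog.mul(factors, axis=0)
    return adjusted / adjusted.sum(axis=0)


def mutation_posterior(channel: str, priors: pd.Series,
                       catalog: pd.DataFrame) -> pd.Series:
    """Posterior signature membership of one mutation.

    posterior_k proportional to catalog_k[channel] * prior_k, normalized over
    the catalogue's signatures.  Priors must sum to one.  A channel with zero
    mass in every signature is undefined and raises.
    """
    if not np.isclose(priors.sum(), 1.0):
        raise ValueError("category priors must sum to 1")
    lik = catalog.loc[channel]
    post = lik * priors.reindex(catalog.columns)
    total = post.sum()
    if total <= 0:
        raise ValueError(f"channel {channel!r} has zero mass in all signatures")
    return post / total


def branch_attribution(channels, priors: pd.Series,
                       catalog: pd.DataFrame) -> pd.Series:
    """Branch-level signature attribution: mean per-mutation posterior.

    Sums the per-mutation membership posteriors over all SNVs assigned to a
    branch and divides by the mutation count, so proportions lie on the
    simplex.  An empty branch is undefined and raises.
    """
    channels = list(channels)
    if not channels:
        raise ValueError("branch has no assigned mutations")
    acc = sum(mutation_posterior(ch, priors, catalog) for ch in channels)
    return acc / len(channels)


def signature_burden_rate(burdens: pd.DataFrame, ages, animals) -> dict:
    """Per-signature burden slope via the random-slope mixed model.

    ``burdens`` has one column per signature (per-colony signature-specific
    burdens); each column is fitted with burden ~ age + (0 + age | animal).
    Returns {signature: fit dict} with slopes in mutations per year.
    """
    return {sig: fit_burden_rate(burdens[sig].to_numpy(), ages, animals)
            for sig in burdens.columns}
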