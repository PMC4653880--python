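"""Convenience orchestration: simulate or ingest a digest, then call the PAM.

Chains the canonical analysis (quality trim -> barcode demux -> perfect
double-flank PAM extraction -> collapse/count -> library normalization ->
PFM -> IUPAC consensus) into a single call, returning every intermediate
for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .assay_sim import (
    CleavageActivityModel,
    DigestCondition,
    ReadEmissionProfile,
    simulate_digest_reads,
)
from .counts import PamCountTable
from .library_design import LibraryScheme
from .pam_model import (
    ConsensusCall,
    PFMatrix,
    call_consensus,
    compute_pfm,
    normalize_counts,
)
from .readproc import SeqRead, process_reads


@dataclass
class PamCallResult:
    """All intermediates of one PAM-discovery pass."""

    counts: PamCountTable
    normalized: PamCountTable
    pfm: PFMatrix
    consensus: ConsensusCall
    qc: dict


def call_pam_from_reads(
    reads: Iterable[SeqRead],
    scheme: LibraryScheme,
    library: PamCountTable,
    barcodes: Mapping[str, str],
    sample: str,
    rnp_conc: float | None = None,
    q_min: int = 13,
    support_threshold: float = 0.9,
    n_floor: float = 0.30,
    pseudocount: float | None = None,
) -> PamCallResult:
    """Run the full read-out chain for one barcoded digest sample.

    Raises ``ValueError`` if no PAMs survive extraction (e.g. a no-RNP
    negative control); inspect the raw tables in that case instead.
    """
    tables, qc = process_reads(
        reads, barcodes,
        left12=scheme.left12, right12=scheme.right12,
        pam_len=scheme.pam_len, q_min=q_min,
        rnp_conc={sample: rnp_conc} if rnp_conc is not None else None,
    )
    counts = tables[sample]
    normalized = normalize_counts(counts, library, pseudocount=pseudocount)
    pfm = compute_pfm(normalized)
    consensus = call_consensus(pfm, support_threshold=support_threshold,
                               n_floor=n_floor)
    return PamCallResult(counts=counts, normalized=normalized, pfm=pfm,
                         consensus=consensus, qc=qc)


def simulate_and_call(
    scheme: LibraryScheme,
    library: PamCountTable,
    model: CleavageActivityModel,
    cond: DigestCondition,
    profile: ReadEmissionProfile,
    n_reads: int,
    seed: int = 0,
    sample: str = "digest",
    **call_kwargs,
) -> PamCallResult:
    """Simulate one digest and run the read-out chain on its reads."""
    reads, _truth = simulate_digest_reads(
        scheme, library, model, cond, profile, n_reads, seed=seed
    )
    return call_pam_from_reads(
        reads, scheme, library, {sample: profile.barcode}, sample,
        rnp_conc=cond.rnp_conc, **call_kwargs,
    )
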