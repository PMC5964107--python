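"""End-to-end convenience pipeline: counts -> filtered per-domain enrichment.

Bacteria are evaluated in the 0.2-3 um size fraction and free viruses in the
0.025-0.2 um fraction; each fraction is normalized and filtered as its own
sample set, then enrichment records are split by taxon domain.
"""

from __future__ import annotations

from typing import Mapping

from .enrichment import EnrichmentRecord, compute_enrichment
from .filters import AbundanceFilterConfig, FilterReport, apply_abundance_filter
from .samples import AbundanceMatrix, Domain, Mode, SizeFraction, TaxonInfo, normalize

__all__ = ["enrichment_by_domain"]

#: Which size fraction each domain is read out of.
DOMAIN_FRACTIONS: dict[Domain, SizeFraction] = {
    Domain.BACTERIA: SizeFraction.F3000_200,
    Domain.VIRUS: SizeFraction.F200_25,
}


def enrichment_by_domain(
    matrix: AbundanceMatrix,
    lineage: Mapping[str, TaxonInfo],
    filter_config: AbundanceFilterConfig | None = None,
    apply_filter: bool = True,
) -> tuple[dict[Domain, list[EnrichmentRecord]], dict[Domain, FilterReport]]:
    """Normalize, filter and compute enrichment separately per size fraction.

    Accepts a counts- or fractions-mode matrix.  Returns per-domain
    enrichment records (bacteria from the large fraction, viruses from the
    small one, each restricted to taxa of that domain) and the per-fraction
    filter reports.
    """
    if matrix.mode is Mode.COUNTS:
        matrix = normalize(matrix)
    records: dict[Domain, list[EnrichmentRecord]] = {}
    reports: dict[Domain, FilterReport] = {}
    for domain, sf in DOMAIN_FRACTIONS.items():
        sub = matrix.subset_size_fraction(sf)
        if not sub.sample_ids:
            continue
        if apply_filter:
            sub, reports[domain] = apply_abundance_filter(sub, filter_config)
        recs = compute_enrichment(sub)
        records[domain] = [
            r
            for r in recs
            if lineage.get(r.taxon_id, TaxonInfo(taxon_id=r.taxon_id)).domain
            is domain
        ]
    return records, reports
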