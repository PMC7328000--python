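"""PSM confidence filtering and parsimony protein inference.

Confidence filtering uses the target-decoy strategy: PSMs against a reversed
("decoy") database estimate the false-discovery rate above a score cutoff,
and the cutoff is set so the estimated FDR is at most a threshold (1% by
default). Protein identities are then inferred by a greedy set cover under
Occam's razor: each peptide is credited ("razor"-assigned) to one protein,
and proteins holding at least two razor peptides are accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .psm_io import PsmRecord, peptide_key

__all__ = ["FdrConfig", "ProteinGroup", "filter_psm_fdr", "infer_proteins", "razor_map"]


@dataclass(frozen=True)
class FdrConfig:
    """Target-decoy FDR threshold (fraction, default 1%)."""

    fdr_threshold: float = 0.01

    def __post_init__(self):
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")


@dataclass
class ProteinGroup:
    """A parsimony protein group.

    ``razor_peptides`` holds the peptide identities (sequence plus
    modification string) credited to this group by the greedy cover;
    ``unique_peptides`` is the subset whose candidate proteins all lie
    inside the group. Acceptance requires >= 2 razor peptides.
    """

    lead_accession: str
    members: set[str] = field(default_factory=set)
    razor_peptides: set[str] = field(default_factory=set)
    unique_peptides: set[str] = field(default_factory=set)
    accepted: bool = False


def filter_psm_fdr(psms, cfg: FdrConfig | None = None) -> list[PsmRecord]:
    """Retain target PSMs above the score cutoff controlling target-decoy FDR.

    The cutoff s* is the smallest score such that
    ``#decoys(score >= s*) / max(1, #targets(score >= s*)) <= fdr_threshold``.
    Decoys never appear in the output. If no cutoff achieves the threshold,
    an empty list is returned with a warning (not an exception).
    """
    cfg = cfg or FdrConfig()
    psms = list(psms)
    targets = [p for p in psms if not p.is_decoy]
    decoys = [p for p in psms if p.is_decoy]
    if not targets:
        return []
    t_scores = sorted(p.score for p in targets)
    d_scores = sorted(p.score for p in decoys)

    import bisect

    def fdr_at(s: float) -> float:
        n_t = len(t_scores) - bisect.bisect_left(t_scores, s)
        n_d = len(d_scores) - bisect.bisect_left(d_scores, s)
        return n_d / max(1, n_t)

    candidates = sorted({p.score for p in psms})
    for s in candidates:
        if fdr_at(s) <= cfg.fdr_threshold:
            return [p for p in targets if p.score >= s]
    warnings.warn(
        f"no score cutoff achieves FDR <= {cfg.fdr_threshold}; returning no PSMs",
        stacklevel=2,
    )
    return []


def infer_proteins(psms) -> list[ProteinGroup]:
    """Greedy set-cover protein inference with razor-peptide acceptance.

    Peptides with identical sequence+modifications collapse to one peptide.
    The cover repeatedly selects the protein explaining the most uncovered
    peptides (ties broken by lexicographically smallest accession), and the
    claimed peptides become that protein's razor peptides. Groups with >= 2
    razor peptides are accepted; a non-accepted protein whose peptide set is
    a subset of an accepted lead's set is folded into that group's members
    (transferring any razor peptides it held). Non-subset leftovers are
    discarded by parsimony.
    """
    pep_proteins: dict[str, set[str]] = {}
    for p in psms:
        pep_proteins.setdefault(p.peptide_key, set()).update(p.proteins)
    prot_peptides: dict[str, set[str]] = {}
    for pep, prots in pep_proteins.items():
        for acc in prots:
            prot_peptides.setdefault(acc, set()).add(pep)
    if not pep_proteins:
        return []

    uncovered = set(pep_proteins)
    selected: list[ProteinGroup] = []
    while uncovered:
        # most uncovered peptides; tie-break on smallest accession
        best = min(
            prot_peptides,
            key=lambda a: (-len(prot_peptides[a] & uncovered), a),
        )
        claimed = prot_peptides[best] & uncovered
        if not claimed:  # unreachable: every peptide names >=1 protein
            break
        selected.append(ProteinGroup(lead_accession=best, razor_peptides=set(claimed)))
        uncovered -= claimed

    for g in selected:
        g.accepted = len(g.razor_peptides) >= 2

    accepted = [g for g in selected if g.accepted]
    accepted.sort(key=lambda g: g.lead_accession)
    selected_leads = {g.lead_accession for g in selected}

    # fold subset proteins into accepted groups
    out: list[ProteinGroup] = list(accepted)
    for g in selected:
        if g.accepted:
            continue
        host = next(
            (
                h
                for h in accepted
                if prot_peptides[g.lead_accession]
                <= prot_peptides[h.lead_accession]
            ),
            None,
        )
        if host is not None:
            host.members.add(g.lead_accession)
            host.razor_peptides |= g.razor_peptides
        else:
            out.append(g)
    for acc in sorted(set(prot_peptides) - selected_leads):
        host = next(
            (h for h in accepted if prot_peptides[acc] <= prot_peptides[h.lead_accession]),
            None,
        )
        if host is not None:
            host.members.add(acc)

    for g in out:
        in_group = g.members | {g.lead_accession}
        g.unique_peptides = {
            pep for pep in g.razor_peptides if pep_proteins[pep] <= in_group
        }
    return out


def razor_map(groups, accepted_only: bool = True) -> dict[str, str]:
    """Peptide identity -> lead accession of the group holding its razor claim."""
    out: dict[str, str] = {}
    for g in groups:
        if accepted_only and not g.accepted:
            continue
        for pep in g.razor_peptides:
            out[pep] = g.lead_accession
    return out
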