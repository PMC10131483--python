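"""Pfam domain accessions used to flag regulatory genes.

Effector-gene screening starts by removing regulatory genes — transcription
factors and cell-signaling components — identified purely by domain content.
The two accession lists below are the curated defaults for the sea urchin
screen; they carry Pfam version suffixes, but matching is always done on the
version-stripped accession so that hit tables produced against any Pfam
release compare equal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

#: Transcription-factor DNA-binding / TF-associated domains.
DEFAULT_TF_ACCESSIONS: frozenset[str] = frozenset({
    "PF01388.17",  # ARID
    "PF02178.15",  # AT_hook
    "PF01586.12",  # Basic
    "PF02376.11",  # CUT
    "PF00751.14",  # DM
    "PF00178.18",  # Ets
    "PF00250.14",  # Forkhead
    "PF00320.23",  # GATA
    "PF03615.11",  # GCM
    "PF00010.22",  # HLH
    "PF00505.15",  # HMG_box
    "PF07527.9",   # Hairy_orange
    "PF00046.25",  # Homeobox
    "PF00104.26",  # Hormone_recep
    "PF03826.13",  # OAR
    "PF00870.14",  # P53
    "PF07710.7",   # P53_tetramer
    "PF00292.14",  # PAX
    "PF00157.13",  # Pou
    "PF05044.8",   # HPD
    "PF00554.18",  # RHD_DNA_bind
    "PF00853.15",  # Runt
    "PF02023.13",  # SCAN
    "PF06621.8",   # SIM_C
    "PF00319.14",  # SRF-TF
    "PF00907.18",  # T-box
    "PF12598.4",   # TBX
    "PF03299.10",  # TF_AP-2
    "PF03529.9",   # TF_Otx
    "PF00170.17",  # bZIP_1
    "PF07716.11",  # bZIP_2
    "PF00096.22",  # zf-C2H2
    "PF01530.14",  # zf-C2HC
    "PF00105.14",  # zf-C4
})

#: Cell-signaling domains (ligands, pathway components, receptor adaptors).
DEFAULT_SIGNALING_ACCESSIONS: frozenset[str] = frozenset({
    "PF04709.8",   # AMH_N
    "PF05337.7",   # CSF-1
    "PF02262.12",  # Cbl_N
    "PF02761.10",  # Cbl_N2
    "PF02762.10",  # Cbl_N3
    "PF01584.15",  # CheW
    "PF00778.13",  # DIX
    "PF02377.11",  # Dishevelled
    "PF00167.14",  # FGF
    "PF03623.9",   # Focal_AT
    "PF00631.18",  # G-gamma
    "PF01109.13",  # GM_CSF
    "PF01627.19",  # Hpt
    "PF07400.7",   # IL11
    "PF03039.10",  # IL12
    "PF00715.13",  # IL2
    "PF02059.11",  # IL3
    "PF00727.14",  # IL4
    "PF02025.11",  # IL5
    "PF01415.12",  # IL7
    "PF00015.17",  # MCPsignal
    "PF03000.10",  # NPH3
    "PF06554.8",   # Olfactory_mark
    "PF00341.13",  # PDGF
    "PF04692.9",   # PDGF_N
    "PF06404.8",   # PSK
    "PF01091.14",  # PTN_MK_C
    "PF05196.9",   # PTN_MK_N
    "PF08916.7",   # Phe_ZIP
    "PF00615.15",  # RGS
    "PF03528.11",  # Rabaptin
    "PF01017.16",  # STAT_alpha
    "PF02864.11",  # STAT_bind
    "PF02865.13",  # STAT_int
    "PF00019.16",  # TGF_beta
    "PF00688.14",  # TGFb_propeptide
    "PF09034.6",   # TRADD_N
    "PF00110.15",  # wnt
})

_VERSION_RE = re.compile(r"\.\d+$")


def strip_accession_version(accession: str) -> str:
    """Drop a trailing Pfam version suffix: ``PF00046.25`` -> ``PF00046``."""
    return _VERSION_RE.sub("", accession.strip())


@dataclass(frozen=True)
class RegulatoryDomainList:
    """The TF and signaling accession sets used by :func:`classify_regulatory`.

    The two sets must be disjoint after version stripping, so that a gene's
    classification reason (``tf`` / ``signaling`` / ``both``) is well defined
    per accession.
    """

    tf_accessions: frozenset[str] = field(default=DEFAULT_TF_ACCESSIONS)
    signaling_accessions: frozenset[str] = field(default=DEFAULT_SIGNALING_ACCESSIONS)

    def __post_init__(self) -> None:
        tf = {strip_accession_version(a) for a in self.tf_accessions}
        sig = {strip_accession_version(a) for a in self.signaling_accessions}
        overlap = tf & sig
        if overlap:
            raise ValueError(
                f"TF and signaling accession sets overlap: {sorted(overlap)}"
            )

    @property
    def tf_bare(self) -> frozenset[str]:
        return frozenset(strip_accession_version(a) for a in self.tf_accessions)

    @property
    def signaling_bare(self) -> frozenset[str]:
        return frozenset(strip_accession_version(a) for a in self.signaling_accessions)
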