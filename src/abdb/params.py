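"""Pipeline-wide tunable parameters.

All geometric thresholds used by the chain-pairing and antigen-classification
rules live here so that a single object can be threaded through the pipeline
and overridden from the CLI or a YAML config file.
"""
from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass
class PipelineParams:
    """Numeric constants of the processing rules.

    contact_cutoff
        Maximum distance (Å) between two atom centres for them to count as a
        contact.  Applied as ``<=``.
    dimer_ca_cutoff
        Maximum distance (Å) between the Cα atoms of positions L36 (and,
        independently, L87) of two light chains for them to be paired as a
        light-chain dimer.
    min_cdr_contacts
        Minimum number of CDR contacts a polymer chain must make with the
        antibody to be classified as antigen (together with making more CDR
        than framework contacts).
    chain_score_threshold
        Percent-identity score (vs. the variable-domain consensus) below which
        a chain that is not the top scorer is demoted to antigen.
    het_min_cdr_contacts
        Minimum number of CDR-involving contacts for a HETATM group to be
        accepted as a hapten antigen.  Haptens are small, so the default is 1.
    cdr_definition
        Which published CDR definition ("kabat" or "chothia") the contact
        rules use when deciding CDR membership of a numbered position.
    multichain_combined
        Whether the >=15-CDR-contact rule for multi-chain antigens is applied
        to the summed contacts of jointly binding chains (True) or per chain.
    """

    contact_cutoff: float = 4.0
    dimer_ca_cutoff: float = 20.0
    min_cdr_contacts: int = 15
    chain_score_threshold: float = 80.0
    het_min_cdr_contacts: int = 1
    cdr_definition: str = "kabat"
    multichain_combined: bool = True

    def __post_init__(self) -> None:
        for name in ("contact_cutoff", "dimer_ca_cutoff", "min_cdr_contacts",
                     "chain_score_threshold", "het_min_cdr_contacts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cdr_definition not in ("kabat", "chothia"):
            raise ValueError("cdr_definition must be 'kabat' or 'chothia'")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)
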