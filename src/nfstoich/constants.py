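"""Physical constants shared by every pipeline stage.

All stages read their constants from here (and echo them into reports) so a
run is fully described by one versioned table.
"""

CONSTANTS_VERSION = "1.0"

#: Avogadro's number used for mass-concentration -> particle-count conversion.
AVOGADRO = 6.0221415e23

#: Molar masses of the neurofilament isoform assays, in Da (g/mol).  The two
#: NfH entries correspond to the SMI35 and SMI34 phosphoform immunoassays.
MOLAR_MASS_DA = {
    "NfL": 68_000.0,
    "NfM": 150_000.0,
    "NfH_SMI35": 200_000.0,
    "NfH_SMI34": 210_000.0,
}

#: Amino-acid counts of the full-length subunits.  Both NfH assay channels
#: report the same 1020-residue protein.
AA_COUNT = {
    "NfL": 543,
    "NfM": 916,
    "NfH": 1020,
}

#: Physiological human NfL:NfM:NfH subunit stoichiometry.
PHYSIOLOGICAL_STOICHIOMETRY = (7.0, 3.0, 2.0)

#: "Adaptive" NfL:NfM:NfH stoichiometry observed in ALS plasma.
ADAPTIVE_STOICHIOMETRY = (24.0, 2.4, 1.6)

#: Mean ATP cost of adding one amino acid to a growing peptide chain.
ATP_PER_AA = 5.0

#: Mean time (seconds) to translate and fold a 100-amino-acid protein.
SECONDS_PER_100_AA = 25.0

ISOFORMS = ("NfL", "NfM", "NfH")
ASSAYS = ("NfL", "NfM", "NfH_SMI35", "NfH_SMI34")


def constants_table() -> dict:
    """Return the full constants table for echoing into run reports."""
    return {
        "version": CONSTANTS_VERSION,
        "avogadro": AVOGADRO,
        "molar_mass_da": dict(MOLAR_MASS_DA),
        "aa_count": dict(AA_COUNT),
        "physiological_stoichiometry": list(PHYSIOLOGICAL_STOICHIOMETRY),
        "adaptive_stoichiometry": list(ADAPTIVE_STOICHIOMETRY),
        "atp_per_aa": ATP_PER_AA,
        "seconds_per_100_aa": SECONDS_PER_100_AA,
    }
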