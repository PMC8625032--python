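"""Shared constants and tunable defaults.

Values here are the package-wide contracts: score cutoffs, atomic radius
tables, filter thresholds. Anything a user might reasonably retune lives
here rather than buried in module code.
"""

# ---- similarity -----------------------------------------------------------
#: Hybrid 3D similarity cutoff separating "similar" from "dissimilar" ligands.
SIMILAR_CUTOFF = 1.2
#: Gaussian amplitude convention for atom-centred shape densities.
GAUSSIAN_P = 2.7
#: Width (Angstrom) of the Gaussian kernel scoring matched pharmacophore pairs.
FEATURE_SIGMA = 1.0

# ---- pose evaluation ------------------------------------------------------
#: RMSD (Angstrom) below which two binding modes count as "similar" / a success.
SUCCESS_RMSD = 2.0
#: Predicted-vs-real binding-site centre distance (Angstrom) beyond which a
#: prediction is considered docked to the wrong site.
SITE_DISTANCE_CUTOFF = 10.0

# ---- conformer generation -------------------------------------------------
MAX_CONFORMERS = 200
CONFORMER_DEDUP_RMSD = 0.5      # Angstrom, symmetry-aware
EMBED_RETRIES = 3

# ---- dataset curation -----------------------------------------------------
MIN_HEAVY_ATOMS = 7
MW_RANGE = (140.0, 800.0)       # Da, inclusive
MIN_BURIED_FRACTION = 0.50
COVALENT_CUTOFF = 1.9           # Angstrom ligand-protein heavy atom distance
POCKET_SHARE_CUTOFF = 8.0       # Angstrom between ligand centres
MULTI_PROTEIN_CONTACT = 4.0     # Angstrom ligand-chain contact distance
SITE_CLUSTER_CUTOFF = 8.0       # Angstrom single-linkage on ligand centres
SASA_PROBE_RADIUS = 1.4         # Angstrom water probe
SASA_N_POINTS = 256             # sphere sample points per atom

# ---- protein matching -----------------------------------------------------
MATCH_MIN_IDENTITY = 0.30       # sequence identity over aligned pairs
BOND_TOLERANCE = 0.45           # Angstrom over covalent-radius sum

# ---- atomic data ----------------------------------------------------------
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39, "B": 0.84, "Se": 1.20,
}

VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98, "B": 1.92, "Se": 1.90,
}
VDW_DEFAULT = 1.70

#: HETATM residue names never treated as the ligand: waters, common ions,
#: buffer and cryo-protectant molecules. Extend per project as needed.
LIGAND_EXCLUDE = frozenset({
    "HOH", "WAT", "DOD",
    "NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE", "CO", "NI", "CU", "CD",
    "IOD", "BR", "F", "LI", "CS", "RB", "SR", "BA", "HG",
    "GOL", "EDO", "PEG", "PGE", "PG4", "MPD", "DMS", "ACT", "SO4", "PO4",
    "NO3", "FMT", "TRS", "EPE", "MES", "IMD", "BME", "DTT",
})
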