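# Default analysis configuration for the Kell protein (UniProt P23276).
protein:
  length: 732
  reference_allele: "KEL*02"

# Topological domains (1-based inclusive residue intervals).
domains:
  IC: [[1, 47]]
  TM: [[48, 67]]
  extracellular: [[68, 732]]
  # Membrane-proximal / membrane-distal subdomain intervals are model-derived
  # and not fixed by sequence; left empty so extracellular positions fall back
  # to "extracellular_unassigned" until a user supplies them.
  MPD: []
  MDD: []

catalog:
  maf_cutoff: 3.0e-05

asa:
  probe_radius: 1.4        # Angstrom, water probe
  n_points: 960            # sphere quadrature points per atom
  include_hetero: false    # exclude hetero atoms (e.g. active-site zinc)

burial:
  buried_max: 0.05         # RSA in [0, 0.05) -> buried
  half_buried_max: 0.25    # RSA in [0.05, 0.25) -> half-buried; [0.25, 1] exposed

membrane:
  threshold: 15.0          # Angstrom; Calpha closer than this counts as proximal
  plane: null              # {point: [x,y,z], normal: [x,y,z]} when known

epitopes:
  linkage_distance: 12.0   # Angstrom between Calpha atoms, single linkage
  # Sequence segments of the predicted conformational epitopes on the Kell
  # extracellular domain (surface helix/loop elements whose antigenic sites
  # co-localize in 3D).
  segments:
    - [139, 147]
    - [244, 260]
    - [287, 299]
    - [300, 310]
    - [322, 333]
    - [379, 392]
    - [399, 407]
    - [483, 496]
    - [589, 601]

profile:
  volume_dz_threshold: 0.5   # |delta-Z| on the volume scale counting as a change
  positive_residues: [R, K, H]
  negative_residues: [D, E]
  hotspot_residues: [R, Q, W, P]

rules:
  conservation_cutoff: 90.0  # percent ortholog identity counting as conserved
  mpc_cutoff: 0.4
  cavity_positions: []       # user-supplied; structural-cavity membership
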