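# Seven-site exciton model of the Fenna-Matthews-Olson (FMO) complex.
#
# Site energies and inter-site couplings (cm^-1) follow the widely used
# structure-based parameterization of the FMO monomer of Prosthecochloris
# aestuarii (Adolphs & Renger, Biophys. J. 91, 2778 (2006), trimer fit);
# energies are quoted relative to the lowest site energy (absolute offset
# 12210 cm^-1 is dynamically irrelevant).  Open-system rates are the values
# conventionally used in FMO transport studies: trapping from pigment 3 into
# the reaction centre at 1 ps^-1, exciton recombination at 1 ns^-1, and
# Markovian pure dephasing of order 1 ps^-1 per site.  All rates are
# editable; this file is data, not code.
#
# Energies are converted internally to angular frequency via
# cm1_to_rad_per_ps = 2*pi*c*(1 cm^-1) = 0.1883651567 rad/ps, so times are
# in picoseconds.

site_energies: [200.0, 320.0, 0.0, 110.0, 270.0, 420.0, 230.0]

couplings:
  - [    0.0, -87.7,   5.5,  -5.9,   6.7, -13.7,  -9.9]
  - [  -87.7,   0.0,  30.8,   8.2,   0.7,  11.8,   4.3]
  - [    5.5,  30.8,   0.0, -53.5,  -2.2,  -9.6,   6.0]
  - [   -5.9,   8.2, -53.5,   0.0, -70.7, -17.0, -63.3]
  - [    6.7,   0.7,  -2.2, -70.7,   0.0,  81.1,  -1.3]
  - [  -13.7,  11.8,  -9.6, -17.0,  81.1,   0.0,  39.7]
  - [   -9.9,   4.3,   6.0, -63.3,  -1.3,  39.7,   0.0]

# rates in ps^-1
dephasing_rate: 1.0
trap_rate: 1.0
recombination_rate: 0.001

trap_site: 3        # pigment feeding the reaction centre
initial_site: 1     # pigment nearest the baseplate/antenna

cm1_to_rad_per_ps: 0.1883651567

# Edge subsets opened for phase optimization: the seven strongest couplings
# (A1) and the three strongest (A2, a subset of A1).
edge_sets:
  A1: [[1, 2], [5, 6], [4, 5], [4, 7], [3, 4], [6, 7], [2, 3]]
  A2: [[1, 2], [5, 6], [4, 5]]
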