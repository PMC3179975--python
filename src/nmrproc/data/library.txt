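# nmrproc metabolite shift library
# Schema: one [metabolite] block per compound, one atom per line:
#   ATOM_LABEL  1H_ppm  13C_ppm
# Synthetic fixture set for testing and demonstration; extend or replace
# with shifts recorded at your own field and sample conditions.

[glutamate]
CA  3.7430  55.5800
CB  2.0400  27.8400
CG  2.3400  34.2400

[lactate]
CA  4.1000  69.3000
CB  1.3300  20.9000

[alanine]
CA  3.7700  51.2000
CB  1.4700  17.0000

[glucose-alpha]
C1  5.2300  92.9000
C2  3.5400  72.3000

[glucose-beta]
C1  4.6400  96.7000
C2  3.2500  75.0000

[myo-inositol]
C2  4.0600  73.0000
C5  3.2700  75.1000
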