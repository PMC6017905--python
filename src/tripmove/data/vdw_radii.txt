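# Per-element van der Waals equilibrium radii (A), AMBER-type R_min/2
# values.  The equilibrium distance of a pair is the sum of the two
# radii; the geometric clash filter rejects non-bonded pairs closer
# than scale_factor times that sum.
C 1.9080
N 1.8240
O 1.6612
S 2.0000
H 1.2000
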