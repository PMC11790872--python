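# Example coastrisk configuration: every value shown here equals the
# shipped default, so this file is a template — uncomment and edit the
# entries you want to override.

[limits]           # standard limit / upper allowable limit, mg/L
# Pb = 0.01
# Cd = 0.003

[rfd]              # oral reference doses, mg/(kg day)
# Pb = 0.0014

[csf]              # oral cancer slope factors, (mg/(kg day))^-1
# Pb = 0.0085

[kp]               # dermal permeability, cm/h
# Pb = 0.0001

[abs]              # gastrointestinal absorption fraction (0, 1]
# Cd = 0.05

[tr]               # toxic-response factors for RI
# Cd = 30.0

[background]       # site background levels for RI, mg/L (required for RI)
# Cd = 0.15

[exposure.adult]
# ir = 2.2        # L/day
# bw = 70.0       # kg
# ed = 30.0       # years
# sa = 18000.0    # cm^2
# et = 0.58       # h/day

[exposure.child]
# ir = 1.0
# bw = 15.0
# ed = 6.0
# sa = 6600.0
# et = 1.0

[mc]
# n = 10000
# seed = 0
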