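# Single-CSS showcase: strong sterility virulence at moderate transmissibility,
# juvenile resistance costing juvenile mortality, adult resistance costing
# reproduction.  Usable with every CLI subcommand, e.g.
#   stageres singular --config examples/config_css.yaml
a0: 5.0
b0: 1.0
g0: 1.0
q: 1.0
beta0: 8.0
f: 0.1
alpha: 0.0
c1J: 0.5
c1A: 0.5
c2J: 3.0
c2A: 3.0
juvenile_target: juvenile_mortality
adult_target: reproduction
rJ: 0.0
rA: 0.0
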