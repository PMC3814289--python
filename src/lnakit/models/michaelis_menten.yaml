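name: michaelis-menten
system_size: 100.0
species:
- id: S
  name: substrate
  initial: 1.0
- id: SE
  name: enzyme-substrate complex
  initial: 0.0
- id: P
  name: product
  initial: 1.0
- id: E
  name: free enzyme
  initial: 10.0
parameters:
  k1: 1.0
  k2: 1.0
  k3: 1.0
  k4: 1.0
  k5: 1.0
reactions:
- id: v1
  products:
    S: 1
  rate: k1
- id: v2
  reactants:
    S: 1
    E: 1
  products:
    SE: 1
  mass_action: k2
- id: v3
  reactants:
    SE: 1
  products:
    S: 1
    E: 1
  mass_action: k3
- id: v4
  reactants:
    SE: 1
  products:
    P: 1
    E: 1
  mass_action: k4
- id: v5
  reactants:
    P: 1
  mass_action: k5
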