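# Generic per-element Lennard-Jones parameters for desk-scale interaction
# energies: sigma in Angstrom, epsilon in kcal/mol.  One entry per element;
# combined across pairs with Lorentz-Berthelot rules.  Users may override
# with their own file of the same shape.
elements:
  H: {sigma: 1.00, epsilon: 0.02}
  C: {sigma: 3.40, epsilon: 0.09}
  N: {sigma: 3.25, epsilon: 0.17}
  O: {sigma: 2.96, epsilon: 0.21}
  S: {sigma: 3.56, epsilon: 0.25}
  P: {sigma: 3.74, epsilon: 0.20}
default: {sigma: 3.40, epsilon: 0.10}
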