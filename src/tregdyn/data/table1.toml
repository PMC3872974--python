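# Canonical parameter set for the Tconv/Treg/IL-2 activation models.
# All rates dimensionless; populations in cells, IL-2 in molecules.

a = 0.4        # proliferation rate of activated T cells [molecules^-1 time^-1]
b = 0.1        # natural death rate of activated T cells and Tregs [time^-1]
c = 1e-5       # fratricide death rate of activated T cells [cells^-1 time^-1]
d = 0.01       # IL-2 secretion rate by activated T cells [molecules cells^-1 time^-1]
e = 0.01       # IL-2 consumption rate [cells^-1 time^-1]
f = 1.0        # IL-2 decay rate [time^-1]
g = 0.1        # natural death rate of naive T cells and resting Tregs [time^-1]
beta = 0.0     # antigen stimulation rate [time^-1]; scanned in [0, inf)
gamma = 0.1    # Treg-mediated suppression rate [cells^-1 time^-1]
epsilon = 0.6  # Treg/Tconv proliferation-rate ratio [-]
N0 = 4.0       # renewal rate of naive T cells [cells time^-1]
lam = 0.006    # relative renewal of resting Tregs vs naive T cells (0.02 = unresponsive case)
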