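# Miniature seed-matched comparison on the synthetic image task:
# a dendritically normalised sparse layer against its unnormalised control.
#   dendronorm train examples/image-mini.cfg --out runs/image-mini

[run]
experiment = train
seed = 0

[train]
m_hidden = 30
epsilon = 0.2
zeta = 0.15
eta = 0.05
minibatch = 10
epochs = 5
n_per_class = 50
n_test_per_class = 20
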