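{
  "izhikevich": {
    "A": {"name": "Tonic spiking", "a": 0.02, "b": 0.2, "c": -65, "d": 6, "xi": 15.1, "I_ext": 0},
    "B": {"name": "Phasic spiking", "a": 0.02, "b": 0.25, "c": -65, "d": 6, "xi": 4.3, "I_ext": 0},
    "C": {"name": "Tonic bursting", "a": 0.02, "b": 0.2, "c": -50, "d": 2, "xi": 15.1, "I_ext": 0},
    "D": {"name": "Phasic bursting", "a": 0.02, "b": 0.25, "c": -55, "d": 0.05, "xi": 4.3, "I_ext": 0},
    "E": {"name": "Mixed mode", "a": 0.02, "b": 0.2, "c": -55, "d": 4, "xi": 15.1, "I_ext": 0},
    "F": {"name": "Spike frequency adaptation", "a": 0.01, "b": 0.2, "c": -65, "d": 8, "xi": 15.1, "I_ext": 0},
    "H": {"name": "Class 2 excitable", "a": 0.2, "b": 0.26, "c": -65, "d": 0, "xi": 5.6, "I_ext": -0.5},
    "J": {"name": "Subthreshold oscillation", "a": 0.05, "b": 0.26, "c": -60, "d": 0, "xi": 1.8, "I_ext": 0},
    "K": {"name": "Resonator", "a": 0.1, "b": 0.26, "c": -60, "d": -1, "xi": 2.4, "I_ext": 0},
    "M": {"name": "Rebound spike", "a": 0.03, "b": 0.25, "c": -60, "d": 4, "xi": 4.5, "I_ext": 0},
    "N": {"name": "Rebound burst", "a": 0.03, "b": 0.25, "c": -52, "d": 0, "xi": 4.5, "I_ext": 0},
    "P": {"name": "Bistability", "a": 0.1, "b": 0.26, "c": -60, "d": 0, "xi": 0.87, "I_ext": 0.24},
    "Q": {"name": "Depolarizing after-potential", "a": 1, "b": 0.2, "c": -60, "d": -21, "xi": 17.8, "I_ext": 0},
    "S": {"name": "Inhibition-induced spiking", "a": -0.02, "b": -1, "c": -60, "d": 8, "xi": 4.5, "I_ext": 80}
  },
  "amat": {
    "A": {"name": "Tonic spiking", "alpha1": 10, "alpha2": 0, "beta": 0},
    "B": {"name": "Phasic spiking", "alpha1": 10, "alpha2": 0, "beta": -0.3},
    "C": {"name": "Tonic bursting", "alpha1": -0.5, "alpha2": 0.35, "beta": 0},
    "D": {"name": "Phasic bursting", "alpha1": -0.5, "alpha2": 0.35, "beta": -0.3},
    "E": {"name": "Mixed mode", "alpha1": -0.8, "alpha2": 0.7, "beta": 0},
    "F": {"name": "Spike frequency adaptation", "alpha1": 10, "alpha2": 1, "beta": 0},
    "G": {"name": "Class 1 excitable", "alpha1": 15, "alpha2": 3, "beta": 0},
    "H": {"name": "Class 2 excitable", "alpha1": 15, "alpha2": -0.05, "beta": 0},
    "I": {"name": "Spike latency", "alpha1": 10, "alpha2": 0, "beta": -1},
    "J": {"name": "Subthreshold oscillations", "alpha1": 1, "alpha2": 0, "beta": 0.2},
    "K": {"name": "Resonator", "alpha1": 10, "alpha2": 0, "beta": 0.5},
    "M": {"name": "Rebound spiking", "alpha1": 10, "alpha2": 0, "beta": -2.5},
    "N": {"name": "Rebound bursting", "alpha1": -0.5, "alpha2": 0.35, "beta": -2.5},
    "O": {"name": "Threshold variability", "alpha1": 10, "alpha2": 0, "beta": -0.5},
    "P": {"name": "Bistability", "alpha1": 20, "alpha2": -0.4, "beta": 0},
    "Q": {"name": "Depolarizing after-potential", "alpha1": 25, "alpha2": -1, "beta": 0},
    "S": {"name": "Inhibition-induced spiking", "alpha1": 20, "alpha2": 0, "beta": 2},
    "T": {"name": "Inhibition-induced bursting", "alpha1": -0.5, "alpha2": 0.35, "beta": 2}
  }
}
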