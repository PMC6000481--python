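item,question,n1,mean1,sd1,n2,mean2,sd2,p_printed
precision,How precisely does your drawing represent your actual sensations?,52,7.31,2.33,51,7.20,3.05,.84
difficulty,How difficult was it to draw your sensations?,52,3.38,2.89,51,1.86,2.16,.003
identification,How well could you identify yourself with the body outline?,52,7.54,2.59,51,8.73,1.71,.007
descriptors,How precisely do the chosen terms describe the nature of your sensations?,52,6.58,2.54,51,7.20,2.47,.21
depth,How difficult was it to evaluate the depth of your sensations?,52,4.71,3.18,51,3.27,2.77,.02
stylus,How precisely do you rate your drawing with the electronic pen in comparison with a pencil drawing?,52,7.52,2.30,51,7.10,3.27,.45
stress,How much physical or mental stress was the drawing of your sensations?,51,1.43,2.18,51,1.65,2.21,.62
instructions,How comprehensible were the drawing instructions for you?,52,7.71,2.41,50,8.32,2.07,.18
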