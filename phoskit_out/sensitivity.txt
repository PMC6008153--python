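perturbation    dP_max %  dalpha %   dbeta %
A_T +1%            +0.72     +0.71   -100.00
A_T -1%            -0.71     -0.71+281341.79
pH +0.01           +1.06     +1.09+7716406.32
pH -0.01           -1.04     -1.11   -100.00
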