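name,sequence,binding_energy
Exendin4-C,HGEGTFTSDLSKQMEEEAVRLFIEWLKNGGPSSGAPPPSC,-50.60
TSME-1,HGEGTFTSDLSMQMEEEAVLLFIEWLMNGGPSSGAPPPSC,-45.88
TSME-2,HGEGTFTSDLSMQMEEEAVFLFIEWLMNGGPSSGAPPPSC,-44.88
TSME-3,HGEGTFTSDLSVQMEEEAVVLFIEWLVNGGPSSGAPPPSC,-43.81
TSME-4,HGEGTFTSDLSMQMEEEAVYLFIEWLMNGGPSSGAPPPSC,-42.93
TSME-5,HGEGTFTSDLSIQMEEEAVYLFIEWLINGGPSSGAPPPSC,-44.33
TSME-6,HGEGTFTSDLSIQMEEEAVVLFIEWLFNGGPSSGAPPPSC,-41.92
TSME-7,HGEGTFTSDLSiQMEEEAVyLFIEWLvNGGPSSGAPPPSC,-40.27
TSME-8,HGEGTFTSDLSvQMEEEAVlLFIEWLvNGGPSSGAPPPSC,-40.91
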