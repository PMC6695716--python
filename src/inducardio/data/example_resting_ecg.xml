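<?xml version="1.0" encoding="ISO-8859-1"?>
<!DOCTYPE RestingECG SYSTEM "rest.dtd">
<RestingECG>
<PatientID>Maria Popescu</PatientID>
<DateofBirth>01-08-1982</DateofBirth>
<Gender>Female</Gender>
<Waveform>
<WaveformType>Rhythm</WaveformType>
<NumberofLeads>1</NumberofLeads>
<SampleType>CONTINUOUS_SAMPLES</SampleType>
<SampleBase>500</SampleBase>
<Battery>Stare incarcare=0, Nivelbaterie=90%, Tensiunebaterie=4,061V</Battery>
<LeadData>
<LeadAmplitudeUnitsPerBit>2.84</LeadAmplitudeUnitsPerBit>
<LeadID>1</LeadID>
<LeadDataCRC32>4291035169</LeadDataCRC32>
<WaveFormData>FF 0000 0000 0000 FF 0000 0000 0000 FF 0000 0000 0000 FF 7FAD 8053 7FB6 FF 7F79 804D 7F6C FF 7E33 802A 7C0D 802D 7C0E FF 7D02 802D 7C0E FF 7D02 802D 7C0F FF 7D02 802D 7C0F FF 7D02 802D 7C0F00000</WaveFormData>
</LeadData>
</Waveform>
</RestingECG>
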