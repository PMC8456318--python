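gene	function	DS1 vs AS1	DS2 vs AS2	DS3 vs AS3	DS4 vs AS4
Pbr039718.1	ACO			+
Pbr008056.1	ACO			-
Pbr022705.1	FUM	+		+	+
Pbr037938.1	IDH			-	+
Pbr027709.3	IDH			+
Pbr024296.3	MDH	+		+	+
Pbr024294.1	MDH	+	+	+	+
Pbr002553.1	MDH				-
Pbr024269.1	MDH			-
Pbr022525.1	MDH			+
Pbr011434.1	MDH	-
Pbr027217.2	MS	-	-
Pbr036933.1	MS		+
Pbr032339.1	OGDH	+	+	+	+
Pbr042601.1	OGDH	+	+	+
Pbr015662.1	OGDH	-	-	-	-
Pbr031234.1	PEPC	+	+	+	+
Pbr017951.1	SDH			-
Pbr033433.1	SDH	+	+	+	+
Pbr022657.1	SDH	-
Pbr007033.1	SDH				+
Pbr014487.1	SDH			+
Pbr024406.1	SDH		-	+
Pbr032250.1	SDH		+
Pbr033391.1	SDH	+	+	+	+
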