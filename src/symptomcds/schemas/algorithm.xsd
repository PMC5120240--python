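<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">

  <xs:simpleType name="identifier">
    <xs:restriction base="xs:string">
      <xs:pattern value="[A-Za-z0-9_.-]+"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="algorithm">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="dictionary" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="variable" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="category" type="xs:string" minOccurs="0" maxOccurs="unbounded"/>
                  </xs:sequence>
                  <xs:attribute name="name" type="identifier" use="required"/>
                  <xs:attribute name="kind" use="required">
                    <xs:simpleType>
                      <xs:restriction base="xs:string">
                        <xs:enumeration value="numeric"/>
                        <xs:enumeration value="categorical"/>
                        <xs:enumeration value="boolean"/>
                        <xs:enumeration value="medication-list"/>
                      </xs:restriction>
                    </xs:simpleType>
                  </xs:attribute>
                  <xs:attribute name="lower" type="xs:decimal"/>
                  <xs:attribute name="upper" type="xs:decimal"/>
                  <xs:attribute name="resolution" type="xs:decimal"/>
                  <xs:attribute name="units" type="xs:string"/>
                  <xs:attribute name="source" type="xs:string"/>
                  <xs:attribute name="inputs" type="xs:string"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:choice maxOccurs="unbounded">
          <xs:element name="node">
            <xs:complexType>
              <xs:sequence>
                <xs:element name="branch" maxOccurs="unbounded">
                  <xs:complexType>
                    <xs:sequence>
                      <xs:element name="predicate">
                        <xs:complexType>
                          <xs:choice>
                            <xs:element name="interval">
                              <xs:complexType>
                                <xs:attribute name="lower" type="xs:decimal" use="required"/>
                                <xs:attribute name="upper" type="xs:decimal" use="required"/>
                                <xs:attribute name="lower-closed" type="xs:boolean" default="true"/>
                                <xs:attribute name="upper-closed" type="xs:boolean" default="true"/>
                              </xs:complexType>
                            </xs:element>
                            <xs:element name="categories">
                              <xs:complexType>
                                <xs:sequence>
                                  <xs:element name="category" type="xs:string" maxOccurs="unbounded"/>
                                </xs:sequence>
                              </xs:complexType>
                            </xs:element>
                            <xs:element name="boolean">
                              <xs:complexType>
                                <xs:attribute name="value" type="xs:boolean" use="required"/>
                              </xs:complexType>
                            </xs:element>
                            <xs:element name="medication-class">
                              <xs:complexType>
                                <xs:attribute name="class" type="xs:string" use="required"/>
                                <xs:attribute name="present" type="xs:boolean" default="true"/>
                              </xs:complexType>
                            </xs:element>
                          </xs:choice>
                          <xs:attribute name="variable" type="identifier" use="required"/>
                        </xs:complexType>
                      </xs:element>
                    </xs:sequence>
                    <xs:attribute name="target" type="identifier" use="required"/>
                  </xs:complexType>
                </xs:element>
              </xs:sequence>
              <xs:attribute name="id" type="identifier" use="required"/>
              <xs:attribute name="variable" type="identifier" use="required"/>
            </xs:complexType>
          </xs:element>
          <xs:element name="terminal">
            <xs:complexType>
              <xs:sequence>
                <xs:element name="recommendation-ref" minOccurs="0" maxOccurs="unbounded">
                  <xs:complexType>
                    <xs:attribute name="id" type="identifier" use="required"/>
                  </xs:complexType>
                </xs:element>
              </xs:sequence>
              <xs:attribute name="id" type="identifier" use="required"/>
            </xs:complexType>
          </xs:element>
        </xs:choice>
      </xs:sequence>
      <xs:attribute name="name" type="identifier" use="required"/>
      <xs:attribute name="root" type="identifier" use="required"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
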